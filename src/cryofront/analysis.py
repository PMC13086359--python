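"""Post-processing: isotherm tracking, log-law growth fits, surface
thermograms, frozen-zone shape metrics.

The frozen zone is characterized by the maximum radial extent R(t) and the
axial depth D(t) of chosen isotherm levels (the -40 degC isotherm is the
conventional lethal boundary for cells; -10 degC is where 5% gelatin
hydrogel visibly turns opaque).  During the freeze stage both follow a
logarithmic growth law a*ln(t+1) to good accuracy, which is what
:func:`fit_log_growth` quantifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import DomainGrid, _as_array

__all__ = [
    "IsothermTrace",
    "GrowthFit",
    "isotherm_radius",
    "isotherm_depth",
    "trace_isotherms",
    "fit_log_growth",
    "surface_thermogram",
    "polar_image",
    "hemiellipsoid_metrics",
]


@dataclass
class IsothermTrace:
    """Time series of max radius R and axial depth D (mm) of one isotherm.

    NaN entries flag instants at which the isotherm is absent."""

    level: float
    times: list[float] = field(default_factory=list)
    R: list[float] = field(default_factory=list)
    D: list[float] = field(default_factory=list)

    def append(self, t: float, R: float, D: float) -> None:
        if self.times and t <= self.times[-1]:
            raise ValueError("trace times must be strictly increasing")
        self.times.append(float(t))
        self.R.append(float(R))
        self.D.append(float(D))

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (np.asarray(self.times), np.asarray(self.R), np.asarray(self.D))

    def at(self, t: float, atol: float = 1e-6) -> tuple[float, float]:
        """(R, D) at the recorded instant closest to t (within atol of it)."""
        times = np.asarray(self.times)
        i = int(np.argmin(np.abs(times - t)))
        if abs(times[i] - t) > atol:
            raise ValueError(f"no trace point at t={t} s (closest: {times[i]} s)")
        return self.R[i], self.D[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.times,
            "level_C": self.level,
            "R_mm": self.R,
            "D_mm": self.D,
        })


@dataclass(frozen=True)
class GrowthFit:
    """Least-squares fit value = offset + slope*ln(t+1), t in seconds.

    The offset is fixed, not fitted: 0 for depth, the applicator radius for
    radius.  The residual RMS (mm) is always reported."""

    slope: float
    offset: float
    residual_rms: float
    n_points: int


def isotherm_radius(fieldlike, grid: DomainGrid, level: float) -> float:
    """Maximum radius (mm) at which T crosses ``level``, NaN if absent.

    Every sample row is searched (the widest frozen extent may sit below the
    surface); within a row the outermost at-or-below-level node is linearly
    interpolated against its outward neighbor.  Ghost/void nodes (the thawing
    cavity) are excluded.
    """
    T = _as_array(fieldlike)
    nz, nr = grid.n_z, grid.n_r
    A = T[1:nz + 1, 1:nr + 1]
    valid = grid.material[1:nz + 1, 1:nr + 1] > 0
    cold = valid & (A <= level)
    rows = np.nonzero(cold.any(axis=1))[0]
    if rows.size == 0:
        return math.nan
    jmax = nr - 1 - np.argmax(cold[rows, ::-1], axis=1)
    r_cold = grid.r[1 + jmax]
    radius = r_cold.copy()
    can_interp = jmax < nr - 1
    if np.any(can_interp):
        jm = jmax[can_interp]
        rr = rows[can_interp]
        T0 = A[rr, jm]
        T1 = A[rr, jm + 1]
        ok = valid[rr, jm + 1] & (T1 > level)
        frac = np.where(ok, (level - T0) / np.where(T1 != T0, T1 - T0, 1.0), 0.0)
        radius[can_interp] = r_cold[can_interp] + frac * grid.dr
    return float(radius.max() * 1e3)


def isotherm_depth(fieldlike, grid: DomainGrid, level: float) -> float:
    """Deepest axial position (mm, at the innermost cell ring standing in for
    r = 0) where T <= ``level``, linearly interpolated; NaN if absent.

    Depth is measured from the undisturbed surface z = 0, so the pressed-in
    applicator plug counts toward it."""
    T = _as_array(fieldlike)
    nz = grid.n_z
    col = T[1:nz + 1, 1]
    valid = grid.material[1:nz + 1, 1] > 0
    cold = valid & (col <= level)
    if not cold.any():
        return math.nan
    imax = int(np.nonzero(cold)[0].max())
    depth = grid.z[1 + imax]
    if imax < nz:  # neighbor below exists in storage (may be the bath row)
        T0 = col[imax] if imax < nz else T[nz, 1]
        T1 = T[1 + imax + 1, 1]
        below_valid = grid.material[1 + imax + 1, 1] > 0
        if below_valid and T1 > level and T1 != T0:
            depth = depth + (level - T0) / (T1 - T0) * grid.dz
    return float(depth * 1e3)


def trace_isotherms(result, levels) -> dict[float, IsothermTrace]:
    """Extract R(t)/D(t) for each level from the snapshots of a
    :class:`~cryofront.solver.SimulationResult`."""
    traces = {lv: IsothermTrace(level=lv) for lv in levels}
    for t, f in zip(result.times, result.fields):
        for lv in levels:
            traces[lv].append(t, isotherm_radius(f, result.grid, lv),
                              isotherm_depth(f, result.grid, lv))
    return traces


def fit_log_growth(trace: IsothermTrace, fixed_offset: float = 0.0,
                   which: str = "D") -> GrowthFit:
    """Least-squares slope of (value - offset) against ln(t+1).

    ``which`` selects the depth ("D") or radius ("R") series.  Instants at
    which the isotherm is absent are dropped; at least 5 valid points are
    required and a constant series is rejected as degenerate.
    """
    t, R, D = trace.arrays()
    y = {"D": D, "R": R}[which] - fixed_offset
    ok = np.isfinite(y)
    t, y = t[ok], y[ok]
    if t.size < 5:
        raise ValueError(f"need >= 5 valid trace points, got {t.size}")
    if np.ptp(y) == 0:
        raise ValueError("degenerate (constant) trace; nothing to fit")
    x = np.log(t + 1.0)
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise ValueError("degenerate abscissa (all t = 0)")
    slope = float(np.dot(x, y) / sxx)
    resid = y - slope * x
    return GrowthFit(slope=slope, offset=fixed_offset,
                     residual_rms=float(np.sqrt(np.mean(resid**2))),
                     n_points=int(t.size))


def surface_thermogram(fieldlike, grid: DomainGrid) -> pd.DataFrame:
    """Surface-row temperatures as a tidy (r_mm, T_C) radial profile.

    This is what an ideal thermal imager pointed at the sample would see
    along a radius; by axial symmetry the full image is concentric circles.
    Applicator-contact and void columns are excluded."""
    T = _as_array(fieldlike)
    cols = np.arange(1, grid.n_r + 1)
    valid = grid.material[1, cols] > 0
    return pd.DataFrame({
        "r_mm": grid.r[cols][valid] * 1e3,
        "T_C": T[1, cols][valid],
    })


def polar_image(profile: pd.DataFrame, n_px: int = 201,
                fill: float = np.nan) -> np.ndarray:
    """Rasterize a radial profile into a square polar-symmetric image.

    Pixel (x, y) takes the profile value at r = sqrt(x^2 + y^2)."""
    r = profile["r_mm"].to_numpy()
    v = profile["T_C"].to_numpy()
    half = r.max()
    ax = np.linspace(-half, half, n_px)
    X, Y = np.meshgrid(ax, ax)
    rad = np.hypot(X, Y)
    img = np.interp(rad, r, v, left=fill, right=fill)
    return img


def hemiellipsoid_metrics(trace: IsothermTrace, t: float) -> float:
    """Depth-to-radius ratio D(t)/R(t) of the frozen hemiellipsoid.

    Below 1 means the frozen zone is an oblate half-ellipsoid whose depth
    lags its surface radius.  Raises if either extent is absent at t."""
    R, D = trace.at(t)
    if not (math.isfinite(R) and math.isfinite(D)):
        raise ValueError(f"isotherm {trace.level} C absent at t={t} s")
    return D / R
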