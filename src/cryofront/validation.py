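"""Independent analytic references and brute-force oracles.

Everything here deliberately avoids the production code paths: the dense
reference stepper is a plain per-node loop re-implementation of the update
rule, and the analytic solutions (semi-infinite erf cooling, the classical
two-phase Neumann solution of the planar Stefan problem) come from closed
forms.  The test suite uses these to validate the solver in its
constant-property and sharp-front limits; they are exported for users who
extend the material library and want the same checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf, erfc

from .grid import DomainGrid, _as_array
from .solver import PropertyTables

__all__ = [
    "NeumannParams",
    "semi_infinite_profile",
    "neumann_lambda",
    "neumann_front_position",
    "reference_step_dense",
]


def semi_infinite_profile(T_init: float, T_wall: float, alpha: float,
                          z, t: float):
    """Temperature of a constant-property half-space whose wall is held at
    T_wall from t = 0: T_wall + (T_init - T_wall) * erf(z / (2 sqrt(alpha t)))."""
    if t <= 0 or alpha <= 0:
        raise ValueError("require t > 0 and alpha > 0")
    z = np.asarray(z, dtype=float)
    out = T_wall + (T_init - T_wall) * erf(z / (2.0 * np.sqrt(alpha * t)))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class NeumannParams:
    """Constant per-phase parameters of the planar two-phase Stefan problem.

    Solid (frozen) phase properties carry subscript s, liquid (unfrozen) l.
    The wall at x = 0 is held at T_wall < T_phase; the liquid starts at
    T_init > T_phase; the front X(t) = 2*lambda*sqrt(alpha_s t) advances into
    the liquid.
    """

    alpha_s: float
    alpha_l: float
    k_s: float
    k_l: float
    L: float
    rho: float
    T_wall: float
    T_phase: float
    T_init: float

    def __post_init__(self) -> None:
        if not (self.T_wall < self.T_phase <= self.T_init):
            raise ValueError("require T_wall < T_phase <= T_init")
        if min(self.alpha_s, self.alpha_l, self.k_s, self.k_l,
               self.L, self.rho) <= 0:
            raise ValueError("all physical parameters must be positive")


def _neumann_residual(lam: float, p: NeumannParams) -> float:
    nu = np.sqrt(p.alpha_s / p.alpha_l)
    solid = (p.k_s * (p.T_phase - p.T_wall) * np.exp(-lam**2)
             / (erf(lam) * np.sqrt(np.pi * p.alpha_s)))
    liquid = (p.k_l * (p.T_init - p.T_phase) * np.exp(-(lam * nu) ** 2)
              / (erfc(lam * nu) * np.sqrt(np.pi * p.alpha_l)))
    return solid - liquid - p.rho * p.L * lam * np.sqrt(p.alpha_s)


def neumann_lambda(params: NeumannParams, bracket: tuple[float, float] = (1e-9, 5.0)
                   ) -> float:
    """Root lambda of the transcendental Stefan balance (residual < 1e-12)."""
    a, b = bracket
    fa, fb = _neumann_residual(a, params), _neumann_residual(b, params)
    if fa * fb > 0:
        raise ValueError("no sign change in bracket; widen it")
    lam = brentq(_neumann_residual, a, b, args=(params,), xtol=1e-15, rtol=1e-15)
    return float(lam)


def neumann_front_position(params: NeumannParams, t) -> float:
    """Front position X(t) = 2*lambda*sqrt(alpha_s t) in meters."""
    lam = neumann_lambda(params)
    t = np.asarray(t, dtype=float)
    out = 2.0 * lam * np.sqrt(params.alpha_s * t)
    return out if out.ndim else float(out)


def reference_step_dense(fieldlike, grid: DomainGrid, tables: PropertyTables,
                         dt: float) -> np.ndarray:
    """One explicit update by an independent dense per-node loop.

    Re-implements the stencil with no masking shortcuts or buffering tricks:
    conductivities are interpolated per node, combined pairwise by the
    harmonic mean, the four fluxes weighted by the half-shifted radii and
    divided by the receiving node's volumetric heat capacity.  Quadratic in
    nodes and pure Python; intended for grids up to ~64x64 in
    oracle-equivalence tests.
    """
    T = _as_array(fieldlike)
    nz2, nr2 = T.shape
    if max(nz2, nr2) > 66:
        raise ValueError("reference stepper is for grids up to 64x64 nodes")
    t0, dT = tables.t0, tables.dT
    n = tables.k.shape[1]

    def interp(tab, m, temp):
        x = min(max((temp - t0) / dT, 0.0), n - 1.000001)
        it = int(x)
        f = x - it
        return tab[m, it] + f * (tab[m, it + 1] - tab[m, it])

    K = np.zeros_like(T)
    for i in range(nz2):
        for j in range(nr2):
            m = grid.material[i, j]
            K[i, j] = 0.0 if m == 0 else interp(tables.k, m, T[i, j])

    def harm(a, b):
        s = a + b
        return 0.0 if s == 0.0 else 2.0 * a * b / (s + 1e-30)

    out = T.copy()
    for i in range(1, nz2 - 1):
        for j in range(1, nr2 - 1):
            m = grid.material[i, j]
            if m == 0 or grid.fixed[i, j]:
                continue
            Tij = T[i, j]
            c = interp(tables.c, m, Tij)
            hu = harm(K[i, j], K[i - 1, j]) * grid.flux_mask_up[i, j]
            hd = harm(K[i, j], K[i + 1, j]) * grid.flux_mask_down[i, j]
            hl = harm(K[i, j], K[i, j - 1]) * grid.flux_mask_left[i, j]
            hr = harm(K[i, j], K[i, j + 1]) * grid.flux_mask_right[i, j]
            flux = (hu * (T[i - 1, j] - Tij) + hd * (T[i + 1, j] - Tij)) / grid.dz**2
            flux += (hr * grid.r_plus[j] * (T[i, j + 1] - Tij)
                     + hl * grid.r_minus[j] * (T[i, j - 1] - Tij)) \
                / (grid.r[j] * grid.dr**2)
            out[i, j] = Tij + dt * flux / c
    return out
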