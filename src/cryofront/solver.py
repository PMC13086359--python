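"""Explicit finite-difference time stepper for the nonlinear axisymmetric
heat equation with freeze/thaw stage handling.

The scheme is forward-Euler on the five-point cylindrical stencil.  Heat-flow
continuity across property jumps (frozen/unfrozen, tissue layers, ghost
nodes) is enforced by combining neighboring conductivities with the
harmonic ("parallel resistors") mean before dividing by the local volumetric
heat capacity; the phase change enters solely through the effective heat
capacity spike inside the mushy interval.

Fixed-temperature nodes (the applicator during freezing, the deep thermal
bath) are skipped by the update, not re-assigned afterwards, so their
outgoing fluxes are physical first-kind boundary conditions; zero-conductivity
ghost nodes implement every no-flux boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .grid import (DomainGrid, SimulationConfig, TemperatureField, _as_array,
                   build_domain, press_applicator, thaw_grid)
from .materials import MaterialLibrary, default_library, mushy_weight_integral

__all__ = [
    "PropertyTables",
    "Stepper",
    "StepperState",
    "SimulationResult",
    "NumericalInstabilityError",
    "interface_conductivity",
    "directional_diffusivities",
    "stable_timestep",
    "step",
    "run_stage",
    "run_freeze_thaw",
    "total_enthalpy",
    "configure_air_layer",
    "build_property_tables",
]

# lookup-table resolution; 0.02 degC resolves the capacity spike at the top
# of the mushy interval while keeping the tables tiny
TABLE_T_MIN = -200.0
TABLE_T_MAX = 45.0
TABLE_DT = 0.02


class NumericalInstabilityError(RuntimeError):
    """Raised when the explicit update produced a non-finite temperature."""


def interface_conductivity(k1, k2):
    """Harmonic-mean conductivity 2*k1*k2/(k1+k2) of two neighboring nodes.

    Equivalent to two series thermal resistors of half the node spacing
    each; returns 0 when either side is a zero-conductivity ghost node.
    """
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    if np.any(k1 < 0) or np.any(k2 < 0):
        raise ValueError("conductivities must be non-negative")
    s = k1 + k2
    out = np.where(s > 0, 2.0 * k1 * k2 / np.where(s > 0, s, 1.0), 0.0)
    return out if out.ndim else float(out)


@dataclass
class PropertyTables:
    """Per-material property lookup tables on a uniform temperature grid.

    ``k`` holds point-sampled conductivity; ``c`` the bin-averaged
    volumetric heat capacity rho*Cp_eff (latent heat folded in exactly, via
    the closed-form mushy-weight integral); ``h`` the cumulative volumetric
    enthalpy consistent with linear interpolation of ``c``.  Row 0 is the
    ghost/void pseudo-material (k = 0, c = 1)."""

    t0: float
    dT: float
    k: np.ndarray   # (n_materials+1, n_points)
    c: np.ndarray
    h: np.ndarray   # cumulative integral of c, same grid

    @property
    def grid_T(self) -> np.ndarray:
        return self.t0 + self.dT * np.arange(self.k.shape[1])

    def lookup(self, tab: np.ndarray, mat: np.ndarray, T: np.ndarray) -> np.ndarray:
        """Vectorized linear interpolation, identical to the kernel's."""
        n = tab.shape[1]
        x = np.clip((np.asarray(T, float) - self.t0) / self.dT, 0.0, n - 1.000001)
        it = x.astype(np.int64)
        f = x - it
        m = np.asarray(mat)
        return tab[m, it] + f * (tab[m, it + 1] - tab[m, it])


def build_property_tables(grid: DomainGrid,
                          library: MaterialLibrary | None = None,
                          mushy: str = "t_squared",
                          air_k_multiplier: float = 400.0,
                          air_rho_cp: float = 2.0e6) -> PropertyTables:
    """Sample the analytic property models onto kernel lookup tables."""
    library = library or default_library()
    tgrid = np.arange(TABLE_T_MIN, TABLE_T_MAX + 0.5 * TABLE_DT, TABLE_DT)
    n = tgrid.size
    nmat = max(grid.material_ids.values(), default=0)
    k_tab = np.zeros((nmat + 1, n))
    c_tab = np.ones((nmat + 1, n))
    edges = np.concatenate([[tgrid[0] - 0.5 * TABLE_DT],
                            tgrid + 0.5 * TABLE_DT])
    for name, mid in grid.material_ids.items():
        model = library.get(name)
        lo, hi = model.valid_range
        k_tab[mid] = model.conductivity(np.clip(tgrid, lo, hi))
        if name == "air_effective":
            k_tab[mid] *= air_k_multiplier
            c_tab[mid] = air_rho_cp
            continue
        Te = np.clip(edges, lo, hi)
        sens = model.density(Te) * model.sensible_cp(Te)
        c_tab[mid] = 0.5 * (sens[:-1] + sens[1:])
        pc = model.phase_change
        if pc is not None and not pc.embedded:
            gint = np.array([
                mushy_weight_integral(a, b, pc, mushy)
                for a, b in zip(edges[:-1], edges[1:])
            ])
            mask = gint > 0
            if np.any(mask):
                mids = np.clip(0.5 * (edges[:-1] + edges[1:])[mask], lo, hi)
                c_tab[mid, mask] += (pc.L_eff * model.density(mids)
                                     * gint[mask] / TABLE_DT)
    # cumulative volumetric enthalpy consistent with linear interp of c
    h_tab = np.zeros_like(c_tab)
    h_tab[:, 1:] = np.cumsum(0.5 * (c_tab[:, :-1] + c_tab[:, 1:]) * TABLE_DT, axis=1)
    return PropertyTables(t0=float(tgrid[0]), dT=TABLE_DT, k=k_tab, c=c_tab, h=h_tab)


def _worst_case_alpha(grid: DomainGrid, tables: PropertyTables) -> dict[int, float]:
    """Max thermal diffusivity bound per material id over the table range.

    Uses max k and min volumetric capacity; for every built-in material both
    extremes occur in the deeply frozen state, so the bound is tight."""
    out = {}
    for mid in grid.material_ids.values():
        kmax = float(tables.k[mid].max())
        cmin = float(tables.c[mid].min())
        out[mid] = kmax / cmin
    return out


def stable_timestep(grid: DomainGrid, tables_or_library=None,
                    safety: float = 0.5, mushy: str = "t_squared") -> float:
    """Largest stable explicit time step times ``safety``.

    Per-node bound: dt <= 1 / [ (a_up + a_down)/dz^2 +
    (a_right*r_plus + a_left*r_minus)/(r_j dr^2) ], minimized over nodes,
    with every diffusivity taken at its worst case over the full (clamped)
    temperature range -- the capacity spike inside the mushy interval only
    slows nodes down, the danger is the high-diffusivity deeply frozen state.
    """
    if not (0 < safety <= 1):
        raise ValueError("safety must be in (0, 1]")
    if isinstance(tables_or_library, PropertyTables):
        tables = tables_or_library
    else:
        tables = build_property_tables(grid, tables_or_library, mushy)
    amax = _worst_case_alpha(grid, tables)
    alpha = np.zeros(grid.shape)
    for mid, a in amax.items():
        alpha[grid.material == mid] = a

    def harm(a, b):
        s = a + b
        return np.where(s > 0, 2 * a * b / np.where(s > 0, s, 1), 0.0)

    a_up = np.zeros_like(alpha)
    a_dn = np.zeros_like(alpha)
    a_lf = np.zeros_like(alpha)
    a_rt = np.zeros_like(alpha)
    a_up[1:, :] = harm(alpha[1:, :], alpha[:-1, :]) * grid.flux_mask_up[1:, :]
    a_dn[:-1, :] = harm(alpha[:-1, :], alpha[1:, :]) * grid.flux_mask_down[:-1, :]
    a_lf[:, 1:] = harm(alpha[:, 1:], alpha[:, :-1]) * grid.flux_mask_left[:, 1:]
    a_rt[:, :-1] = harm(alpha[:, :-1], alpha[:, 1:]) * grid.flux_mask_right[:, :-1]
    denom = (a_up + a_dn) / grid.dz**2 \
        + (a_rt * grid.r_plus[None, :] + a_lf * grid.r_minus[None, :]) \
        / (grid.r[None, :] * grid.dr**2)
    updated = (grid.material > 0) & ~grid.fixed
    dmax = float(denom[updated].max()) if np.any(updated) else 0.0
    if dmax <= 0:
        raise ValueError("no updated nodes; cannot derive a time step")
    return safety / dmax


@dataclass
class StepperState:
    """Mutable integration state: field, conductivity cache, clock, stage."""

    field: TemperatureField
    K: np.ndarray
    elapsed: float = 0.0
    stage: str = "freeze"


@dataclass
class SimulationResult:
    """Snapshots plus per-level isotherm traces of one simulated stage."""

    stage: str
    dt: float
    n_steps: int
    times: list[float] = field(default_factory=list)
    fields: list[TemperatureField] = field(default_factory=list)
    traces: dict = field(default_factory=dict)   # level -> analysis.IsothermTrace
    diagnostics: dict = field(default_factory=dict)
    grid: DomainGrid | None = None

    @property
    def final(self) -> TemperatureField:
        return self.fields[-1]


class Stepper:
    """Bundles grid, tables and buffers; drives the compiled kernel."""

    def __init__(self, grid: DomainGrid, library: MaterialLibrary | None = None,
                 mushy: str = "t_squared", air_k_multiplier: float = 400.0,
                 air_rho_cp: float = 2.0e6):
        self.grid = grid
        self.library = library or default_library()
        self.tables = build_property_tables(
            grid, self.library, mushy, air_k_multiplier, air_rho_cp)
        self.upd = ((grid.material > 0) & ~grid.fixed).astype(np.float64)
        # interior no-update on the border ring except the surface film row
        self.upd[:, 0] = 0.0
        self.upd[:, -1] = 0.0
        self.upd[-1, :] = 0.0
        self.top_active = bool(np.any(self.upd[0, :] > 0))
        self._K = np.zeros(grid.shape)
        self._HV = np.zeros(grid.shape)
        self._HH = np.zeros(grid.shape)
        # precomputed radial stencil weights r_plus/(r_j dr^2), r_minus/(r_j dr^2)
        self._wr = grid.r_plus / (grid.r * grid.dr**2)
        self._wl = grid.r_minus / (grid.r * grid.dr**2)
        self._buf = None

    def stable_timestep(self, safety: float = 0.5) -> float:
        return stable_timestep(self.grid, self.tables, safety)

    def advance(self, fieldlike, dt: float, nsteps: int = 1) -> np.ndarray:
        """Run ``nsteps`` explicit updates in place; returns the array."""
        T = _as_array(fieldlike)
        if T.shape != self.grid.shape:
            raise ValueError("field shape does not match grid storage shape")
        if self._buf is None or self._buf.shape != T.shape:
            self._buf = T.copy()
        else:
            self._buf[:, :] = T
        g, t = self.grid, self.tables
        try:
            _kernels.run_chunk(
                T, self._buf, self._K, self._HV, self._HH, g.material, self.upd,
                t.k, t.c, t.t0, 1.0 / t.dT,
                self._wr, self._wl, dt, 1.0 / g.dz**2,
                g.flux_mask_up, g.flux_mask_down,
                g.flux_mask_left, g.flux_mask_right,
                nsteps, self.top_active,
            )
        except (ZeroDivisionError, FloatingPointError, OverflowError) as exc:
            # a runaway temperature corrupted the table lookup mid-chunk
            raise NumericalInstabilityError(
                "non-finite temperatures during the explicit update; "
                "the scheme went unstable -- reduce dt"
            ) from exc
        if not np.all(np.isfinite(T)):
            i, j = np.argwhere(~np.isfinite(T))[0]
            raise NumericalInstabilityError(
                f"non-finite temperature at node (i={i}, j={j}) "
                f"(z={self.grid.z[i]*1e3:.3g} mm, r={self.grid.r[j]*1e3:.3g} mm); "
                "the explicit scheme went unstable -- reduce dt"
            )
        return T


def step(state: StepperState, grid: DomainGrid, library: MaterialLibrary | None,
         dt: float, stepper: Stepper | None = None) -> StepperState:
    """Single explicit update of ``state`` (thin wrapper over :class:`Stepper`)."""
    stepper = stepper or Stepper(grid, library)
    stepper.advance(state.field, dt, 1)
    _kernels.refresh_conductivity(state.field.T, grid.material, stepper.tables.k,
                                  stepper.tables.t0, 1.0 / stepper.tables.dT,
                                  state.K)
    state.elapsed += dt
    state.field.time += dt
    return state


def directional_diffusivities(fieldlike, grid: DomainGrid,
                              library_or_tables=None,
                              mushy: str = "t_squared"):
    """Effective diffusivity fields (a_up, a_down, a_left, a_right).

    Each is the harmonic-mean pair conductivity toward that neighbor divided
    by the local volumetric heat capacity, with the direction flux masks
    applied; nodes facing a ghost get exactly 0 in that direction."""
    if isinstance(library_or_tables, PropertyTables):
        tables = library_or_tables
    else:
        tables = build_property_tables(grid, library_or_tables, mushy)
    T = _as_array(fieldlike)
    K = tables.lookup(tables.k, grid.material, T)
    K[grid.material == 0] = 0.0
    C = tables.lookup(tables.c, grid.material, T)
    out = []
    for shift, mask in (((-1, 0), grid.flux_mask_up),
                        ((1, 0), grid.flux_mask_down),
                        ((0, -1), grid.flux_mask_left),
                        ((0, 1), grid.flux_mask_right)):
        Kn = np.roll(K, (-shift[0], -shift[1]), axis=(0, 1))
        a = interface_conductivity(K, Kn) / C * mask
        # roll wraps the border ring; those entries are never used by the
        # stencil but zero them for cleanliness
        if shift[0] == -1:
            a[0, :] = 0.0
        elif shift[0] == 1:
            a[-1, :] = 0.0
        elif shift[1] == -1:
            a[:, 0] = 0.0
        else:
            a[:, -1] = 0.0
        out.append(a)
    return tuple(out)


def total_enthalpy(fieldlike, grid: DomainGrid, library_or_tables=None,
                   T_ref: float = 0.0, mushy: str = "t_squared") -> float:
    """Total enthalpy (J) of all non-ghost nodes relative to ``T_ref``.

    Integrates the same interpolated volumetric capacity the kernel uses, so
    closed-domain conservation can be checked to round-off."""
    if isinstance(library_or_tables, PropertyTables):
        tables = library_or_tables
    else:
        tables = build_property_tables(grid, library_or_tables, mushy)
    T = _as_array(fieldlike)
    m = grid.material
    live = m > 0

    def H(temps, mats):
        n = tables.c.shape[1]
        x = np.clip((temps - tables.t0) / tables.dT, 0.0, n - 1.000001)
        it = x.astype(np.int64)
        f = x - it
        c0 = tables.c[mats, it]
        c1 = tables.c[mats, it + 1]
        return tables.h[mats, it] + (c0 * f + 0.5 * (c1 - c0) * f * f) * tables.dT

    dH = H(T[live], m[live]) - H(np.full(live.sum(), float(T_ref)), m[live])
    vol = grid.cell_volumes()[live]
    return float(np.sum(dH * vol))


def configure_air_layer(grid: DomainGrid, config: SimulationConfig) -> DomainGrid:
    """Turn the surface boundary row outside the applicator footprint into an
    effective-air film (thin, calibratable surrogate for sidewall convection
    and frost; produces the frozen surface ring).  No-op when disabled."""
    if not config.air_layer:
        return grid
    if "air_effective" not in grid.material_ids:
        grid.material_ids["air_effective"] = max(grid.material_ids.values()) + 1
    aid = grid.material_ids["air_effective"]
    cols = np.ones(grid.n_r + 2, dtype=bool)
    cols[[0, -1]] = False
    cols &= ~(grid.applicator[0, :] | grid.fixed[0, :])
    grid.air[0, cols] = True
    grid.material[0, cols] = aid
    return grid


def _resolve_dt(config: SimulationConfig, stepper: Stepper) -> float:
    if config.dt == "auto":
        return stepper.stable_timestep(config.safety)
    return float(config.dt)


def run_stage(config: SimulationConfig, stage: str,
              initial: TemperatureField | None = None,
              grid: DomainGrid | None = None,
              library: MaterialLibrary | None = None,
              trace_levels: tuple[float, ...] | None = None,
              progress: bool = False) -> SimulationResult:
    """Integrate one stage (``freeze`` or ``thaw``) of the schedule.

    Freeze: applicator fixed at T_N, deep bath at T_b, no-flux sides, the
    optional surface air film active.  Thaw: the applicator volume becomes a
    no-flux cavity and the whole sample--air interface is insulated; the bath
    stays.  Isotherm radius/depth traces are recorded every
    ``config.trace_interval`` seconds without storing the field; full
    snapshots follow ``config.snapshot_interval`` (final field always kept).
    """
    from . import analysis  # deferred: analysis imports grid only

    if stage not in ("freeze", "thaw"):
        raise ValueError(f"unknown stage {stage!r}")
    library = library or default_library()
    if grid is None:
        grid = build_domain(config, library)
        grid, init0 = press_applicator(grid, config)
        if config.air_layer:
            configure_air_layer(grid, config)
        if initial is None:
            initial = init0
    elif initial is None:
        raise ValueError("an initial field is required with a prebuilt grid")
    if stage == "thaw":
        grid = thaw_grid(grid)

    duration = config.freeze_duration if stage == "freeze" else config.thaw_duration
    levels = tuple(trace_levels if trace_levels is not None
                   else config.isotherm_levels)
    field0 = initial.copy()
    t_start = field0.time

    stepper = Stepper(grid, library, config.mushy_weight,
                      config.air_k_multiplier, config.air_rho_cp)
    result = SimulationResult(stage=stage, dt=0.0, n_steps=0, grid=grid)
    result.traces = {lv: analysis.IsothermTrace(level=lv) for lv in levels}

    def record(fieldlike, t):
        for lv in levels:
            result.traces[lv].append(
                t,
                analysis.isotherm_radius(fieldlike, grid, lv),
                analysis.isotherm_depth(fieldlike, grid, lv),
            )

    def snapshot(fieldlike, t):
        result.times.append(t)
        result.fields.append(TemperatureField(fieldlike.T.copy(), t))

    record(field0, t_start)
    if duration <= 0:
        snapshot(field0, t_start)
        return result

    dt0 = _resolve_dt(config, stepper)
    interval = min(config.trace_interval, duration)
    n_sub = max(1, math.ceil(interval / dt0))
    dt = interval / n_sub
    n_intervals = math.ceil(duration / interval - 1e-9)
    result.dt = dt

    snap_every = (max(1, round(config.snapshot_interval / interval))
                  if config.snapshot_interval else None)
    T = field0.T
    prev = T.copy()
    for k in range(1, n_intervals + 1):
        stepper.advance(T, dt, n_sub)
        result.n_steps += n_sub
        t = t_start + k * interval
        record(TemperatureField(T, t), t)
        if snap_every and k % snap_every == 0:
            snapshot(TemperatureField(T, t), t)
        result.diagnostics.setdefault("max_dT_per_interval", []).append(
            float(np.abs(T - prev).max()))
        prev[:, :] = T
        if progress and k % 10 == 0:
            print(f"  [{stage}] t = {t - t_start:.1f}/{duration:.1f} s", flush=True)
    t_end = t_start + n_intervals * interval
    if not result.times or result.times[-1] != t_end:
        snapshot(TemperatureField(T, t_end), t_end)
    result.diagnostics["dt"] = dt
    result.diagnostics["n_steps"] = result.n_steps
    return result


def run_freeze_thaw(config: SimulationConfig,
                    library: MaterialLibrary | None = None,
                    progress: bool = False
                    ) -> tuple[SimulationResult, SimulationResult | None]:
    """Run the configured freeze stage and, if scheduled, the thaw stage
    continuing from the freeze-stage final field."""
    freeze = run_stage(config, "freeze", library=library, progress=progress)
    thaw = None
    if config.thaw_duration > 0:
        thaw = run_stage(config, "thaw", initial=freeze.final,
                         grid=freeze.grid, library=library, progress=progress)
    return freeze, thaw
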