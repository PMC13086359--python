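"""Axisymmetric (z, r) computational domain construction.

The domain is a cylinder of sample material seen in the (depth, radius)
half-plane.  Storage arrays are (N_z+2) x (N_r+2): one border ring around the
simulated nodes implements all boundary conditions without special-casing the
stencil.

Layout conventions (see also the methods note):

* z is depth, positive downward, 0 at the undisturbed sample surface.
* radial nodes are cell-centered, r_j = (j + 1/2) * dr, so the axis r = 0 is
  a cell face and the half-shifted radius r_minus of the innermost cell is
  exactly 0 -- no axis singularity and no inward flux through the axis.
* storage row 0 is the surface boundary row (cell centers at z = -dz/2): the
  applicator contact footprint (fixed at T_N), optionally the effective-air
  film, and no-flux ghost elsewhere.
* storage row N_z+1 is the deep thermal bath: fixed at T_b with normal
  conductivity (Dirichlet via skipped update).
* storage columns 0 and N_r+1 are zero-conductivity ghost nodes (no-flux at
  the axis by symmetry and at the outer wall).
* material id 0 means ghost/void: zero conductivity, never updated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .materials import MaterialLibrary, default_library

__all__ = [
    "SimulationConfig",
    "DomainGrid",
    "TemperatureField",
    "build_domain",
    "layer_stack",
    "press_applicator",
    "thaw_grid",
]

GHOST = 0  # material id of ghost/void nodes


@dataclass
class SimulationConfig:
    """Geometry, grid, schedule and boundary settings of one simulation.

    Lengths are meters, times seconds, temperatures degrees Celsius.  The
    user-facing config files (TOML/JSON, see :mod:`cryofront.cli_io`) use
    millimeters and are converted on load.
    """

    r_max: float = 12e-3
    z_max: float = 12e-3
    n_r: int = 256
    n_z: int = 256
    r_ap: float = 4e-3       # applicator tip radius
    z_ap: float = 1e-3       # press-in depth
    T_N: float = -196.0      # applicator temperature (boiling LN2)
    T_b: float = 34.0        # bath / initial temperature
    freeze_duration: float = 30.0
    thaw_duration: float = 0.0
    dt: float | str = "auto"
    safety: float = 0.5      # fraction of the explicit stability bound
    material_set: str = "hydrogel"   # "hydrogel" | "tissue"
    skin_thickness: float = 0.6e-3
    fat_thickness: float = 0.3e-3
    air_layer: bool = False
    # effective-film defaults stand in for sidewall convection and frost:
    # k = 400 x molecular air (~10 W/(m K)) and a frost-like heat capacity
    air_k_multiplier: float = 400.0
    air_rho_cp: float = 2.0e6        # J/(m^3 K), effective surface film
    isotherm_levels: tuple[float, ...] = (0.0, -10.0, -40.0)
    trace_interval: float = 1.0
    snapshot_interval: float | None = None   # None: keep only the final field
    mushy_weight: str = "t_squared"

    def __post_init__(self) -> None:
        problems = []
        if self.r_max <= 0 or self.z_max <= 0:
            problems.append("domain extents must be positive")
        if self.n_r <= 0 or self.n_z <= 0:
            problems.append("node counts must be positive")
        if not (0 < self.r_ap < self.r_max):
            problems.append("require 0 < r_ap < r_max")
        if not (0 <= self.z_ap < self.z_max):
            problems.append("require 0 <= z_ap < z_max")
        if self.freeze_duration < 0 or self.thaw_duration < 0:
            problems.append("stage durations must be non-negative")
        if not isinstance(self.dt, str) and self.dt <= 0:
            problems.append("dt must be positive or 'auto'")
        if isinstance(self.dt, str) and self.dt != "auto":
            problems.append(f"dt must be a number or 'auto', got {self.dt!r}")
        if not (0 < self.safety <= 1):
            problems.append("safety must be in (0, 1]")
        if self.material_set not in ("hydrogel", "tissue"):
            problems.append(f"unknown material_set {self.material_set!r}")
        if self.skin_thickness < 0 or self.fat_thickness < 0:
            problems.append("layer thicknesses must be non-negative")
        if self.skin_thickness + self.fat_thickness >= self.z_max:
            problems.append("skin + fat must be thinner than the domain depth")
        if self.trace_interval <= 0:
            problems.append("trace_interval must be positive")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))

    @property
    def dr(self) -> float:
        return self.r_max / self.n_r

    @property
    def dz(self) -> float:
        return self.z_max / self.n_z


@dataclass
class TemperatureField:
    """Node-centered temperatures (degC) on the storage grid at one instant."""

    T: np.ndarray
    time: float = 0.0

    def copy(self) -> "TemperatureField":
        return TemperatureField(self.T.copy(), self.time)


def _as_array(fieldlike) -> np.ndarray:
    return fieldlike.T if isinstance(fieldlike, TemperatureField) else np.asarray(fieldlike)


@dataclass
class DomainGrid:
    """Mesh geometry plus the material / boundary masks of one stage."""

    n_z: int
    n_r: int
    dz: float
    dr: float
    z: np.ndarray          # storage-indexed cell-center depths, length n_z+2
    r: np.ndarray          # storage-indexed cell-center radii, length n_r+2
    r_plus: np.ndarray     # half-shifted outer radii, storage-indexed
    r_minus: np.ndarray    # half-shifted inner radii, storage-indexed
    material: np.ndarray   # int8 (n_z+2, n_r+2); 0 = ghost/void
    fixed: np.ndarray      # bool: node temperature never updated
    applicator: np.ndarray  # bool: applicator-occupied nodes (incl. contact row)
    air: np.ndarray        # bool: effective-air film nodes (surface row)
    material_ids: dict[str, int] = field(default_factory=dict)  # name -> id >= 1
    flux_mask_up: np.ndarray | None = None
    flux_mask_down: np.ndarray | None = None
    flux_mask_left: np.ndarray | None = None
    flux_mask_right: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = (self.n_z + 2, self.n_r + 2)
        for name in ("material", "fixed", "applicator", "air"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} mask must have storage shape {shape}")
        ones = lambda: np.ones(shape, dtype=np.float64)
        if self.flux_mask_up is None:
            self.flux_mask_up = ones()
        if self.flux_mask_down is None:
            self.flux_mask_down = ones()
        if self.flux_mask_left is None:
            self.flux_mask_left = ones()
        if self.flux_mask_right is None:
            self.flux_mask_right = ones()

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_z + 2, self.n_r + 2)

    @property
    def interior(self) -> tuple[slice, slice]:
        """Slices of the simulated sample block (rows 1..n_z, cols 1..n_r)."""
        return (slice(1, self.n_z + 1), slice(1, self.n_r + 1))

    def id_of(self, name: str) -> int:
        return self.material_ids[name]

    def name_of(self, mid: int) -> str:
        for k, v in self.material_ids.items():
            if v == mid:
                return k
        raise KeyError(mid)

    def cell_volumes(self) -> np.ndarray:
        """Annular cell volumes 2*pi*r_j*dr*dz, storage-indexed (n_z+2, n_r+2)."""
        vr = 2.0 * np.pi * self.r * self.dr * self.dz
        return np.broadcast_to(vr, self.shape).copy()

    def copy(self) -> "DomainGrid":
        return replace(
            self,
            material=self.material.copy(),
            fixed=self.fixed.copy(),
            applicator=self.applicator.copy(),
            air=self.air.copy(),
            material_ids=dict(self.material_ids),
            flux_mask_up=self.flux_mask_up.copy(),
            flux_mask_down=self.flux_mask_down.copy(),
            flux_mask_left=self.flux_mask_left.copy(),
            flux_mask_right=self.flux_mask_right.copy(),
        )


def build_domain(config: SimulationConfig,
                 library: MaterialLibrary | None = None) -> DomainGrid:
    """Build the mesh and material layout (without the applicator).

    Cell-centered radii r_j = (j+1/2)*dr make r_plus - r_minus = dr exactly
    and put r_minus = 0 on the innermost ring, which encodes the axis
    symmetry without a coordinate singularity.
    """
    library = library or default_library()
    nz, nr = config.n_z, config.n_r
    dz, dr = config.dz, config.dr
    # storage index i -> depth of cell center; row 0 sits above the surface
    z = (np.arange(nz + 2) - 0.5) * dz
    r = (np.arange(nr + 2) - 0.5) * dr
    r_plus = r + 0.5 * dr
    r_minus = np.maximum(r - 0.5 * dr, 0.0)

    shape = (nz + 2, nr + 2)
    material = np.zeros(shape, dtype=np.int8)
    fixed = np.zeros(shape, dtype=bool)
    applicator = np.zeros(shape, dtype=bool)
    air = np.zeros(shape, dtype=bool)

    grid = DomainGrid(
        n_z=nz, n_r=nr, dz=dz, dr=dr, z=z, r=r,
        r_plus=r_plus, r_minus=r_minus,
        material=material, fixed=fixed, applicator=applicator, air=air,
    )
    layer_stack(grid, config, library)
    return grid


def layer_stack(grid: DomainGrid, config: SimulationConfig,
                library: MaterialLibrary | None = None) -> np.ndarray:
    """Assign material ids to the sample block as depth-ordered bands.

    Tissue set: skin on [0, t_skin), subcutaneous fat on
    [t_skin, t_skin + t_fat), muscle below.  Hydrogel set: uniform
    hydrogel_5pct.  A zero-thickness layer is simply omitted; a layer thinner
    than dz (but nonzero) is unresolvable and raises, instructing grid
    refinement.  The deep-bath boundary row inherits the deepest material so
    its Dirichlet nodes conduct with physical k.
    """
    library = library or default_library()
    nz, nr = grid.n_z, grid.n_r
    if config.material_set == "hydrogel":
        bands = [("hydrogel_5pct", 0.0, config.z_max)]
    else:
        t_s, t_f = config.skin_thickness, config.fat_thickness
        for nm, t in (("skin", t_s), ("subcutaneous_fat", t_f)):
            if 0 < t < grid.dz:
                raise ValueError(
                    f"{nm} layer ({t*1e3:.3g} mm) is thinner than dz "
                    f"({grid.dz*1e3:.3g} mm); refine the grid so every layer "
                    "spans at least one node row"
                )
        bands = []
        if t_s > 0:
            bands.append(("skin", 0.0, t_s))
        if t_f > 0:
            bands.append(("subcutaneous_fat", t_s, t_s + t_f))
        bands.append(("muscle", t_s + t_f, config.z_max))

    names = [nm for nm, _, _ in bands]
    if config.air_layer:
        names.append("air_effective")
    ids = {}
    for nm in names:
        library.get(nm)  # raises on unknown material
        if nm not in ids:
            ids[nm] = len(ids) + 1
    grid.material_ids = ids

    zc = grid.z[1:nz + 1]
    for nm, lo, hi in bands:
        rows = 1 + np.nonzero((zc >= lo) & (zc < hi))[0]
        grid.material[rows, 1:nr + 1] = ids[nm]
    # deep thermal bath: fixed T_b, normal conductivity of the deepest layer
    grid.material[nz + 1, 1:nr + 1] = grid.material[nz, 1:nr + 1]
    grid.fixed[nz + 1, :] = True
    return grid.material


def press_applicator(grid: DomainGrid, config: SimulationConfig
                     ) -> tuple[DomainGrid, TemperatureField]:
    """Mark the pressed-in applicator and build the initial temperature field.

    Nodes with r <= r_ap, z < z_ap (ownership by cell center) are held at T_N
    for the whole freeze stage; the surface boundary row repeats the fixed
    T_N contact inside the footprint so a z_ap = 0 (surface-contact only)
    configuration still cools the sample.  One-way heat flow into the sample
    falls out of the update rule: fixed nodes are skipped by the stepper, so
    the sample can never warm the applicator, while the applicator conducts
    into the sample with physical k.
    """
    nz, nr = grid.n_z, grid.n_r
    in_r = grid.r <= config.r_ap
    in_r[0] = False
    in_r[nr + 1] = False

    # contact row: footprint nodes take the surface material and are fixed
    grid.applicator[0, in_r] = True
    grid.material[0, in_r] = grid.material[1, in_r]
    grid.fixed[0, in_r] = True

    in_z = grid.z < config.z_ap
    in_z[0] = False
    plug = np.outer(in_z, in_r)
    grid.applicator |= plug
    grid.fixed |= plug

    if config.air_layer:
        air_cols = np.ones(nr + 2, dtype=bool)
        air_cols[[0, nr + 1]] = False
        air_cols &= ~in_r
        grid.air[0, air_cols] = True
        grid.material[0, air_cols] = grid.material_ids["air_effective"]

    T = np.full(grid.shape, config.T_b, dtype=np.float64)
    T[grid.applicator] = config.T_N
    return grid, TemperatureField(T, 0.0)


def thaw_grid(grid: DomainGrid) -> DomainGrid:
    """Boundary masks for the thaw stage: the applicator volume becomes a
    no-flux void (its cavity exchanges no heat with the sample), and the
    surface air film, if any, is switched off -- heat transfer through the
    sample-air interface is neglected during thawing.  The deep bath keeps
    its fixed temperature."""
    g = grid.copy()
    g.material[g.applicator] = GHOST
    g.material[g.air] = GHOST
    g.fixed[g.applicator] = False
    g.air[:] = False
    return g
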