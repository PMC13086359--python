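# Methods

## Physical model

We solve transient heat conduction in a cylinder of sample material under a
flat disk cryoapplicator, assuming axial symmetry: temperature T(z, r, t)
with z the depth below the undisturbed surface (positive downward) and r
the distance from the applicator axis.  All three thermophysical properties
— density ρ(T), thermal conductivity k(T) and heat capacity C_p(T) — are
temperature dependent, which matters because the simulated span (−196 °C at
the applicator to +34 °C in the body) changes k of frozen gel by a factor
of ~4 and C_p by a factor of ~3.

No metabolic heat source or blood perfusion term is included: the freeze
stage is short (tens of seconds) relative to perfusion time scales, and the
hydrogel phantom the model is calibrated against has neither.  Convection
in the melt is ignored (gels are solid); moisture transport is ignored.

### Phase change

Gels and tissues are solutions: ice forms progressively between the
cryoscopic temperature T_f (first ice) and the initial melting temperature
T_m (freezable water exhausted), e.g. [−0.1, −14] °C for 5% gelatin.  We
therefore use the enthalpy method: the latent heat L_eff (= L·f_FW·w for
the gel: 334 kJ/kg × 0.93 freezable fraction × 0.95 moisture = 295 kJ/kg)
is spread over the mushy interval as an addition to the heat capacity,

    Cp_eff(T) = Cp(T) + L_eff · g(T),   ∫_{T_m}^{T_f} g dT = 1.

The default weight g(T) ∝ T_f/T² concentrates the release just below T_f
(about half the latent heat sits in the top 0.1 °C for the gel), matching
how dilute solutions actually freeze.  The proportionality constant is
chosen so g integrates to exactly 1; `mushy_weight` also accepts
`"printed"` (the same shape with a slightly deficient normalization, kept
for comparison), `"uniform"` and `"linear"`.  The binding contract, checked
by tests, is the normalization: the excess of Cp_eff over Cp must integrate
to L_eff within 1%.

Muscle is special: its tabulated capacity branches already include the
latent contribution ("embedded"), so no g-term is added.  The effective
surface-air medium has no phase change.

### Material library

`data/materials.json` (documented schema in the file) carries piecewise
polynomial and rational branches for hydrogel, skin, subcutaneous fat and
muscle, in strict SI units internally (J/(kg·K), W/(m·K), kg/m³;
temperatures stay in °C because every source polynomial is written in °C —
the gel capacity branch is printed in kJ/(kg·K) and carries an explicit
×1000 scale).  Branches are evaluated half-open on the low side, [T_lo,
T_hi).  Outside the tabulated range (below −160 °C for the gel, −50 °C for
tissues) the source data are extrapolations anyway, so properties are
clamped to their boundary values and a warning is issued once per material.

Two transcription quirks are implemented as printed and flagged here
rather than "fixed": the gel's mushy-range density branch is discontinuous
with its neighbors at T_f (≈1016 vs ≈936 kg/m³), and the frozen-muscle
conductivity contains a (T + T_f) term where (T − T_f) would be
conventional — the printed form is in fact nearly continuous with the
unfrozen branch at T_f, so it is plausibly intentional.

## Discretization

Explicit forward-Euler on a five-point stencil.  The radial mesh is
cell-centered, r_j = (j+½)Δr: the axis r = 0 is then a cell *face*, the
half-shifted radii satisfy r₊ − r₋ = Δr with r₋ = 0 on the innermost ring
(no axis singularity, zero inward flux), and the radial update weights
r₊/r_j, r₋/r_j make the scheme exactly the conservative finite-volume
discretization — with uniform properties total enthalpy is conserved to
round-off, which the tests check.

Unlike-material and unlike-temperature neighbors exchange heat through the
harmonic mean 2k₁k₂/(k₁+k₂) of their conductivities (two series resistors
of half a cell each), evaluated fresh from the current field every step and
once per edge.

Boundaries use a one-node border ring:

* zero-conductivity ghost nodes implement every no-flux condition (axis by
  symmetry, outer wall, thawing-stage surface);
* fixed-temperature nodes (the applicator at −196 °C during freezing, the
  deep thermal bath at the sample's initial temperature) are simply never
  updated, so their fluxes into the sample are physical first-kind boundary
  conditions while their own temperature never responds — the one-way
  coupling that models an applicator whose cooling power dwarfs the
  incoming heat;
* the surface row above the sample holds the applicator contact footprint
  and, optionally, the effective air film.

The applicator is pressed z_ap = 1 mm into the sample by default: nodes
with r ≤ r_ap, z < z_ap start at −196 °C and stay fixed through the freeze
stage.  During thawing the applicator volume is re-masked as a
zero-conductivity void (the cavity exchanges no heat) and the entire
sample–air interface becomes no-flux.

### Properties in the inner loop

The compiled kernel reads k(T) and ρ·Cp_eff(T) from per-material lookup
tables sampled every 0.02 °C over [−200, 45] °C and linearly interpolated.
The capacity table is *bin-averaged from the exact volumetric enthalpy*
(closed-form integral of g per bin), so the latent heat contained in any
traversed interval is represented exactly at table resolution — a node
cannot lose latent heat to table discretization.  A node stepping clear
across the narrow capacity spike in one update can still under-absorb
latent heat; this is inherent to explicit enthalpy methods, and the
Neumann–Stefan validation below bounds its effect on front position.

### Stability

The explicit scheme requires dt ≤ 1/[(α↑+α↓)/Δz² + (α→r₊+α←r₋)/(r_jΔr²)]
at every node.  `stable_timestep` bounds each material's diffusivity by
max k / min (ρCp_eff) over its whole clamped temperature range — for all
built-in media both extremes occur deep in the frozen state, so the bound
is tight; the capacity spike inside the mushy interval only makes nodes
more sluggish, never unstable.  `dt="auto"` applies a safety factor of 0.5.
A non-finite temperature aborts the run with the offending node named.

### Effective surface-air film

The cryoapplicator's uninsulated side walls cool the surrounding air, which
together with frost deposition freezes a thin surface ring around the main
ice spot.  Resolving convection and frost is out of scope; instead the
surface row outside the footprint can carry an *effective* film whose
conductivity is molecular air (0.026 W/(m·K)) times a calibration
multiplier and whose volumetric capacity is frost-like.  The defaults
(multiplier 400 → ≈10 W/(m·K), ρC_p = 2·10⁶ J/(m³·K)) are chosen on the
physical scale of convective + frost-mediated transport and produce the
documented qualitative behavior — a sub-zero annulus wider than the
conduction-only frozen radius; molecular-air values provably cannot, since
the frozen gel itself conducts two orders of magnitude better.  The film is
off by default and none of the reproduced headline numbers depend on it;
multiplier → 0 recovers the no-film field continuously.

## Problem sizes

Chosen as the package's defaults for a single CPU:

* 30 s freeze (growth-law fits): 256×256 over 12×12 mm, dt ≈ 0.1 ms.
* 30 min freeze (hemiellipsoid morphometry): 160×150 over 30×28 mm
  (≈0.19 mm/node), dt ≈ 1.7 ms; the domain is ≥1.3× the final frozen
  extent in each direction so the no-flux side walls stay passive.
* 15 s visible-ice radius: 192×192 over 12×12 mm.
* fat-thickness sweep: 100×100 over 10×10 mm, Δz = 0.1 mm so the 0.5 mm
  skin and 0.3–1.0 mm fat bands are node-resolved.

Grid convergence of the 30 s frozen depth between 80² and 160² (dt/4) is
under 2%, and 128²→256² changes the growth-law slopes by ~1%.

## Validation

* **Oracle equivalence**: a pure-Python dense per-node re-implementation of
  the update rule agrees with the compiled kernel to 1e-12 relative on
  random fields including fixed and ghost nodes.
* **erf limit**: constant-property semi-infinite cooling matches
  T_wall + (T_init−T_wall)·erf(z/2√(αt)) within 1% of the span at
  z = 1–4 mm, t = 1–10 s.
* **Stefan limit**: with constant per-phase properties and the mushy
  interval narrowed to 0.2 °C, the simulated front tracks the classical
  two-phase Neumann solution X(t) = 2λ√(α_s t) (λ from bracketed root
  solving, residual < 1e-12) within 2% for t ∈ [5, 50] s at Δz = 20 µm,
  converging as the mesh is refined.
* **Conservation**: closed domains conserve total enthalpy to round-off
  with constant properties and to ~1e-8 with smoothly varying
  temperature-dependent properties.  Fields straddling the latent-heat
  spike at near-stability dt do *not* conserve to that level (nodes can
  vault the spike); front-position accuracy is governed by the Stefan test
  above.

## What the simulations do and do not show

The tests exercise the solver under the same idealizations the model makes:
perfect, instantaneous −196 °C contact over the footprint from t = 0
(boundary condition of the first kind; a real applicator measures −192 to
−194.8 °C and couples through a contact resistance), no room-air heat
input during long exposures, property polynomials extrapolated below their
coldest tabulated data, and tissue layers of uniform thickness.
Consequently early-time frozen-zone growth runs systematically hot —
the simulated visible-ice radius 15 s into a gel freeze is ~7.5 mm against
~6 mm measured — while half-hour milestones land within ~10% of
morphometry; and without the (author-calibrated, unpublished) air film the
radius growth slope of the −40 °C isotherm fits ~0.85 mm/ln(s) against the
published 1.03.  Passing tests certify the numerics and the stated physics,
not the fidelity of those idealizations to any particular bench setup.
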