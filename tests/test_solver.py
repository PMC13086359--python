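"""Stepper correctness: interface conductivities, oracle equivalence,
conservation, stability control, stage handling and the air film."""

import numpy as np
import pytest

from cryofront.grid import (SimulationConfig, TemperatureField, build_domain,
                            press_applicator)
from cryofront.materials import MaterialLibrary
from cryofront.solver import (NumericalInstabilityError, Stepper,
                              build_property_tables, directional_diffusivities,
                              interface_conductivity, run_stage,
                              stable_timestep, total_enthalpy)
from cryofront.validation import reference_step_dense

from conftest import closed_box


def test_interface_conductivity_values():
    assert interface_conductivity(0.7, 0.7) == pytest.approx(0.7)
    assert interface_conductivity(1.0, 3.0) == pytest.approx(1.5)
    assert interface_conductivity(0.0, 5.0) == 0.0
    # harmonic mean of the printed unfrozen skin/fat pair
    assert interface_conductivity(0.424, 0.223) == pytest.approx(0.2923, abs=2e-4)
    with pytest.raises(ValueError):
        interface_conductivity(-0.1, 1.0)


def test_directional_diffusivities_uniform_medium(const_library):
    g = closed_box(16, lib=const_library)
    T = np.full(g.shape, 20.0)
    a_up, a_dn, a_lf, a_rt = directional_diffusivities(T, g, const_library)
    alpha = 0.5 / (1000.0 * 3000.0)
    core = (slice(3, 14), slice(3, 14))
    for a in (a_up, a_dn, a_lf, a_rt):
        np.testing.assert_allclose(a[core], alpha, rtol=1e-12)
    # nodes facing the ghost ring get exactly zero in that direction
    assert np.all(a_up[1, 1:-1] == 0.0)
    assert np.all(a_dn[16, 1:-1] == 0.0)
    assert np.all(a_rt[1:-1, 16] == 0.0)


def test_uniform_field_is_stationary(const_library):
    g = closed_box(16, lib=const_library)
    st = Stepper(g, const_library)
    T = np.full(g.shape, 17.0)
    st.advance(T, st.stable_timestep(0.9), 50)
    np.testing.assert_allclose(T[g.interior], 17.0, atol=1e-12)


def test_axial_update_matches_1d_stencil(const_library):
    """A radially uniform field has no radial fluxes; one step must equal the
    classical 1D explicit update T + alpha dt (T_up - 2T + T_dn)/dz^2."""
    g = closed_box(16, lib=const_library)
    st = Stepper(g, const_library)
    rng = np.random.default_rng(3)
    profile = 10 + 10 * rng.random(16)
    T = np.full(g.shape, profile[-1])
    T[1:17, :] = profile[:, None]
    alpha = 0.5 / (1000.0 * 3000.0)
    dt = st.stable_timestep(0.5)
    lap = np.zeros(16)
    lap[1:-1] = profile[2:] - 2 * profile[1:-1] + profile[:-2]
    lap[0] = profile[1] - profile[0]      # no-flux ends
    lap[-1] = profile[-2] - profile[-1]
    expected = profile + alpha * dt * lap / g.dz**2
    st.advance(T, dt, 1)
    np.testing.assert_allclose(T[1:17, 8], expected, rtol=1e-12)


def test_step_equals_dense_reference_oracle(library, small_freeze_setup):
    """Oracle equivalence: the compiled stepper and the independent per-node
    dense loop agree to 1e-12 relative on random fields, including fixed
    applicator nodes and ghost boundaries."""
    cfg, g, f0 = small_freeze_setup
    st = Stepper(g, library)
    dt = st.stable_timestep(0.5)
    rng = np.random.default_rng(7)
    upd = (g.material > 0) & ~g.fixed
    for _ in range(15):
        T = f0.T.copy()
        T[upd] = -60 + 90 * rng.random(int(upd.sum()))
        ref = reference_step_dense(T, g, st.tables, dt)
        out = T.copy()
        st.advance(out, dt, 1)
        err = np.abs(out - ref) / np.maximum(np.abs(ref), 1.0)
        assert err.max() < 1e-12


def test_stable_timestep_closed_form(const_library):
    """Constant alpha, dz = dr = h: the bound reduces to
    safety / (2 alpha (1/dz^2 + 1/dr^2)) = safety h^2/(4 alpha)."""
    alpha = 0.5 / (1000.0 * 3000.0)
    g = closed_box(16, extent=8e-3, lib=const_library)
    h = g.dz
    dt = stable_timestep(g, const_library, safety=0.5)
    assert dt == pytest.approx(0.5 * h**2 / (4 * alpha), rel=1e-9)
    g2 = closed_box(8, extent=8e-3, lib=const_library)  # doubled spacing
    dt2 = stable_timestep(g2, const_library, safety=0.5)
    assert dt2 == pytest.approx(4 * dt, rel=1e-9)


def test_enthalpy_conservation_constant_properties(const_library):
    g = closed_box(24, lib=const_library)
    st = Stepper(g, const_library)
    rng = np.random.default_rng(0)
    T = np.full(g.shape, 20.0)
    T[g.material > 0] = 10 + 20 * rng.random(576)
    H0 = total_enthalpy(T, g, st.tables)
    st.advance(T, st.stable_timestep(0.9), 1000)
    assert abs(total_enthalpy(T, g, st.tables) - H0) / abs(H0) < 1e-9


def test_enthalpy_conservation_temperature_dependent(library):
    """Closed box of hydrogel with a smooth resolved warm bump: drift stays
    below 1e-6 of the total even though rho, k, Cp all vary with T."""
    g = closed_box(24, lib=library)
    st = Stepper(g, library)
    Z, R = np.meshgrid(g.z, g.r, indexing="ij")
    T = 18.0 + 12.0 * np.exp(-((Z - 3e-3)**2 + (R - 3e-3)**2) / (1.5e-3)**2)
    H0 = total_enthalpy(T, g, st.tables)
    st.advance(T, st.stable_timestep(0.5), 1000)
    assert abs(total_enthalpy(T, g, st.tables) - H0) / abs(H0) < 1e-6


def test_total_enthalpy_reference_and_scaling(const_library):
    g = closed_box(12, lib=const_library)
    T = np.full(g.shape, 25.0)
    assert total_enthalpy(T, g, const_library, T_ref=25.0) == 0.0
    h1 = total_enthalpy(T, g, const_library, T_ref=0.0)
    g2 = closed_box(12, lib=const_library)
    g2.dz *= 2          # doubled cell height doubles every cell volume
    h2 = total_enthalpy(T, g2, const_library, T_ref=0.0)
    assert h2 == pytest.approx(2 * h1, rel=1e-12)


def test_discrete_maximum_principle(const_library):
    g = closed_box(20, lib=const_library)
    st = Stepper(g, const_library)
    rng = np.random.default_rng(11)
    T = np.full(g.shape, 20.0)
    T[g.material > 0] = 5 + 30 * rng.random(400)
    lo, hi = T[g.material > 0].min(), T[g.material > 0].max()
    st.advance(T, st.stable_timestep(0.9), 300)
    inner = T[g.material > 0]
    assert inner.min() >= lo - 1e-9
    assert inner.max() <= hi + 1e-9


def test_instability_is_diagnosed(const_library):
    g = closed_box(16, lib=const_library)
    st = Stepper(g, const_library)
    rng = np.random.default_rng(2)
    T = np.full(g.shape, 20.0)
    T[g.material > 0] = 40 * rng.random(256)
    with pytest.raises(NumericalInstabilityError, match="reduce dt"):
        st.advance(T, 40 * st.stable_timestep(1.0), 2000)


def test_zero_duration_stage_returns_initial(library):
    cfg = SimulationConfig(n_r=16, n_z=16, r_max=8e-3, z_max=8e-3,
                           freeze_duration=0.0, isotherm_levels=(0.0,))
    res = run_stage(cfg, "freeze", library=library)
    g = res.grid
    sample = (g.material > 0) & ~g.applicator
    assert np.all(res.final.T[sample] == cfg.T_b)
    assert res.n_steps == 0


def test_run_stage_rejects_unknown_stage(library):
    cfg = SimulationConfig(n_r=16, n_z=16, r_max=8e-3, z_max=8e-3)
    with pytest.raises(ValueError, match="unknown stage"):
        run_stage(cfg, "refreeze", library=library)


def _surface_ring_width(res, r_ap):
    """Outermost sub-zero surface radius beyond the bulk frozen spot."""
    from cryofront.analysis import surface_thermogram
    prof = surface_thermogram(res.final, res.grid)
    cold = prof[prof.T_C < 0.0]
    return cold.r_mm.max() if len(cold) else 0.0


@pytest.mark.parametrize("seconds", [20.0])
def test_air_film_produces_frozen_surface_ring(library, seconds):
    """With the effective air film on, a frozen annulus forms on the surface
    beyond the conduction-only frozen radius; with the multiplier driven to
    zero the film decouples and the no-film field is recovered."""
    base = dict(n_r=64, n_z=64, r_max=12e-3, z_max=12e-3,
                freeze_duration=seconds, isotherm_levels=(0.0,),
                trace_interval=5.0)
    off = run_stage(SimulationConfig(**base), "freeze", library=library)
    on = run_stage(SimulationConfig(air_layer=True, **base), "freeze",
                   library=library)
    r_off = _surface_ring_width(off, 4.0)
    r_on = _surface_ring_width(on, 4.0)
    assert r_on > r_off + 0.2   # the ring extends the sub-zero surface zone

    zeroed = run_stage(SimulationConfig(air_layer=True, air_k_multiplier=0.0,
                                        **base), "freeze", library=library)
    sample = (off.grid.material > 0) & ~off.grid.applicator
    np.testing.assert_allclose(zeroed.final.T[sample], off.final.T[sample],
                               atol=1e-9)


def test_thaw_stage_monotone_decay(library):
    """Removing the applicator lets stored cold redistribute briefly, after
    which the frozen zone only shrinks: past its maximum, R of the 0 degC
    isotherm is non-increasing and ends below its freeze-end value."""
    cfg = SimulationConfig(n_r=48, n_z=48, r_max=12e-3, z_max=12e-3,
                           freeze_duration=20.0, thaw_duration=120.0,
                           isotherm_levels=(0.0,), trace_interval=5.0)
    freeze = run_stage(cfg, "freeze", library=library)
    thaw = run_stage(cfg, "thaw", initial=freeze.final, grid=freeze.grid,
                     library=library)
    tr = thaw.traces[0.0]
    R = np.asarray(tr.R)
    ok = np.isfinite(R)
    R = R[ok]
    k = int(np.argmax(R))
    assert k < len(R) - 2             # the transient is short
    assert np.all(np.diff(R[k:]) <= 1e-6)
    assert R[-1] < R[0]
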