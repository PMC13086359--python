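"""Isotherm extraction, growth-law fitting, thermograms, shape metrics."""

import math

import numpy as np
import pytest

from cryofront.analysis import (IsothermTrace, fit_log_growth,
                                hemiellipsoid_metrics, isotherm_depth,
                                isotherm_radius, polar_image,
                                surface_thermogram, trace_isotherms)
from cryofront.grid import SimulationConfig, build_domain
from cryofront.solver import run_stage


@pytest.fixture()
def uniform_grid(library):
    cfg = SimulationConfig(n_r=40, n_z=40, r_max=10e-3, z_max=10e-3)
    return build_domain(cfg, library)


def test_radius_absent_in_warm_field(uniform_grid):
    T = np.full(uniform_grid.shape, 34.0)
    assert math.isnan(isotherm_radius(T, uniform_grid, 0.0))
    assert math.isnan(isotherm_depth(T, uniform_grid, 0.0))


def test_radius_exact_for_linear_synthetic_field(uniform_grid):
    g = uniform_grid
    T = np.empty(g.shape)
    T[:, :] = -50.0 + 10.0 * (g.r[None, :] * 1e3)   # crosses 0 at r = 5 mm
    assert isotherm_radius(T, g, 0.0) == pytest.approx(5.0, rel=1e-12)
    # any other level is linear too: -10 degC at 4 mm
    assert isotherm_radius(T, g, -10.0) == pytest.approx(4.0, rel=1e-12)


def test_depth_exact_for_linear_synthetic_field(uniform_grid):
    g = uniform_grid
    T = np.empty(g.shape)
    T[:, :] = -50.0 + 25.0 * (g.z[:, None] * 1e3)   # crosses 0 at z = 2 mm
    assert isotherm_depth(T, g, 0.0) == pytest.approx(2.0, rel=1e-12)


def test_radius_of_annulus_counts_outermost_crossing(uniform_grid):
    """A detached cold ring (as produced by sidewall air cooling) extends the
    reported maximum radius to its outer edge."""
    g = uniform_grid
    T = np.full(g.shape, 20.0)
    r_mm = g.r * 1e3
    ring = (r_mm >= 6.0) & (r_mm <= 7.0)
    T[1, ring] = -5.0
    R = isotherm_radius(T, g, 0.0)
    assert R > 7.0 - g.dr * 1e3
    assert R < 7.0 + g.dr * 1e3


def test_fit_recovers_exact_log_law():
    tr = IsothermTrace(level=-40.0)
    for t in range(31):
        tr.append(float(t), 4.0 + 1.5 * math.log(t + 1), 2.0 * math.log(t + 1))
    fit_D = fit_log_growth(tr, 0.0, "D")
    assert fit_D.slope == pytest.approx(2.0, rel=1e-12)
    assert fit_D.residual_rms == pytest.approx(0.0, abs=1e-12)
    fit_R = fit_log_growth(tr, 4.0, "R")
    assert fit_R.slope == pytest.approx(1.5, rel=1e-12)


def test_fit_recovers_slope_from_noisy_trace():
    rng = np.random.default_rng(5)
    sigma, s_true = 0.05, 1.303
    tr = IsothermTrace(level=-40.0)
    t = np.arange(1, 31, dtype=float)
    x = np.log(t + 1)
    noise = rng.normal(0.0, sigma, t.size)
    for ti, xi, ni in zip(t, x, noise):
        tr.append(ti, 4.0, s_true * xi + ni)
    fit = fit_log_growth(tr, 0.0, "D")
    stderr = sigma / math.sqrt(float(np.dot(x, x)))
    assert abs(fit.slope - s_true) < 3 * stderr
    assert fit.residual_rms < 3 * sigma


def test_fit_rejects_degenerate_input():
    tr = IsothermTrace(level=0.0)
    for t in range(6):
        tr.append(float(t), 4.0, 3.0)
    with pytest.raises(ValueError, match="degenerate"):
        fit_log_growth(tr, 0.0, "D")
    short = IsothermTrace(level=0.0)
    short.append(0.0, 1.0, 1.0)
    with pytest.raises(ValueError, match=">= 5"):
        fit_log_growth(short, 0.0, "D")


def test_trace_times_strictly_increasing():
    tr = IsothermTrace(level=0.0)
    tr.append(0.0, 1.0, 1.0)
    with pytest.raises(ValueError, match="strictly increasing"):
        tr.append(0.0, 2.0, 2.0)


def test_thermogram_flat_for_uniform_field(uniform_grid):
    T = np.full(uniform_grid.shape, 21.5)
    prof = surface_thermogram(T, uniform_grid)
    assert list(prof.columns) == ["r_mm", "T_C"]
    assert np.all(prof.T_C == 21.5)
    assert prof.r_mm.is_monotonic_increasing


def test_polar_image_matches_radial_profile(uniform_grid):
    T = np.empty(uniform_grid.shape)
    T[:, :] = -30.0 + 4.0 * (uniform_grid.r[None, :] * 1e3)
    prof = surface_thermogram(T, uniform_grid)
    img = polar_image(prof, n_px=101)
    c = 50
    half = prof.r_mm.max()
    ax = np.linspace(-half, half, 101)
    for px in (60, 75, 90):
        r = math.hypot(ax[px], ax[c])
        expected = np.interp(r, prof.r_mm.to_numpy(), prof.T_C.to_numpy())
        assert img[c, px] == pytest.approx(expected, rel=1e-12)


def test_hemiellipsoid_ratio():
    tr = IsothermTrace(level=-10.0)
    tr.append(10.0, 5.0, 5.0)
    tr.append(20.0, 20.0, 17.8)
    assert hemiellipsoid_metrics(tr, 10.0) == pytest.approx(1.0)
    assert hemiellipsoid_metrics(tr, 20.0) == pytest.approx(0.89)
    tr.append(30.0, float("nan"), 3.0)
    with pytest.raises(ValueError, match="absent"):
        hemiellipsoid_metrics(tr, 30.0)


@pytest.fixture(scope="module")
def short_freeze(library):
    cfg = SimulationConfig(n_r=64, n_z=64, r_max=10e-3, z_max=10e-3,
                           freeze_duration=10.0,
                           isotherm_levels=(0.0, -10.0, -40.0),
                           snapshot_interval=2.0)
    return run_stage(cfg, "freeze", library=library)


def test_freeze_traces_monotone_and_nested(short_freeze):
    """During freezing every isotherm only grows, and colder isotherms stay
    nested inside warmer ones."""
    for lv, tr in short_freeze.traces.items():
        R = np.asarray(tr.R)
        D = np.asarray(tr.D)
        for series in (R, D):
            s = series[np.isfinite(series)]
            assert np.all(np.diff(s) >= -1e-9), f"level {lv} not monotone"
    t0, R0, D0 = short_freeze.traces[0.0].arrays()
    for lv in (-10.0, -40.0):
        _, R, D = short_freeze.traces[lv].arrays()
        ok = np.isfinite(R)
        assert np.all(R[ok] <= R0[ok] + 1e-9)
        ok = np.isfinite(D)
        assert np.all(D[ok] <= D0[ok] + 1e-9)


def test_snapshot_reextraction_matches_online_traces(short_freeze):
    """trace_isotherms applied to stored snapshots reproduces the traces the
    solver recorded on the fly at the same instants."""
    res = short_freeze
    re = trace_isotherms(res, (0.0, -40.0))
    online = res.traces
    for lv in (0.0, -40.0):
        for t, R, D in zip(re[lv].times, re[lv].R, re[lv].D):
            i = online[lv].times.index(t)
            assert R == pytest.approx(online[lv].R[i], nan_ok=True)
            assert D == pytest.approx(online[lv].D[i], nan_ok=True)


def test_depth_lags_radius_in_hydrogel(short_freeze):
    """The frozen zone is an oblate hemiellipsoid: D/R < 1 throughout."""
    tr = short_freeze.traces[0.0]
    for t in tr.times[2:]:
        assert hemiellipsoid_metrics(tr, t) < 1.0
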