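"""Shared fixtures: the built-in material library, synthetic constant-property
media, and small prebuilt domains."""

from __future__ import annotations

import numpy as np
import pytest

from cryofront.grid import SimulationConfig, build_domain, press_applicator
from cryofront.materials import (Branch, MaterialLibrary, MaterialModel,
                                 PhaseChangeSpec, PiecewiseModel,
                                 default_library)


@pytest.fixture(scope="session")
def library():
    return default_library()


def make_constant_material(name="hydrogel_5pct", k=0.5, rho=1000.0, cp=3000.0):
    """Single-branch constant-property medium (no phase change)."""
    pw = lambda v: PiecewiseModel((Branch(-200.0, 45.0, (("poly", (v,)),)),))
    return MaterialModel(name=name, valid_range=(-200.0, 45.0),
                         density_model=pw(rho), conductivity_model=pw(k),
                         sensible_cp_model=pw(cp), phase_change=None)


def make_two_phase_material(name="hydrogel_5pct", k_s=2.2, k_l=0.6,
                            rho=1000.0, cp=2000.0, T_f=-1.0, T_m=-1.2,
                            L=300000.0):
    """Constant per-phase properties with a narrow mushy window; the
    enthalpy method then approximates a sharp Stefan front."""
    def pw(frozen, unfrozen):
        return PiecewiseModel((Branch(-200.0, T_f, (("poly", (frozen,)),)),
                               Branch(T_f, 45.0, (("poly", (unfrozen,)),))))
    return MaterialModel(name=name, valid_range=(-200.0, 45.0),
                         density_model=pw(rho, rho),
                         conductivity_model=pw(k_s, k_l),
                         sensible_cp_model=pw(cp, cp),
                         phase_change=PhaseChangeSpec(T_f=T_f, T_m=T_m, L_eff=L))


@pytest.fixture()
def const_library():
    return MaterialLibrary({"hydrogel_5pct": make_constant_material()})


def closed_box(n=24, extent=6e-3, lib=None):
    """n x n sample block with no-flux (ghost) borders and no fixed nodes."""
    cfg = SimulationConfig(r_max=extent, z_max=extent, n_r=n, n_z=n,
                           r_ap=extent / 3, z_ap=0.0, freeze_duration=1.0)
    g = build_domain(cfg, lib)
    g.fixed[:] = False
    g.material[:, :] = 0
    g.material[1:n + 1, 1:n + 1] = 1
    return g


@pytest.fixture()
def small_freeze_setup(library):
    """16x16 hydrogel domain with the pressed-in applicator and initial field."""
    cfg = SimulationConfig(r_max=8e-3, z_max=8e-3, n_r=16, n_z=16,
                           z_ap=1e-3, freeze_duration=5.0,
                           isotherm_levels=(0.0, -10.0, -40.0))
    g = build_domain(cfg, library)
    g, f0 = press_applicator(g, cfg)
    return cfg, g, f0
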