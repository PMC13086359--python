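"""Temperature-dependent thermophysical property models.

Every medium the simulator knows about -- 5% gelatin hydrogel, skin,
subcutaneous fat, muscle and the effective surface-air medium -- is described
by piecewise temperature-dependent models for density, thermal conductivity
and sensible heat capacity, plus phase-change constants.  The latent heat of
the water-ice transition is not tracked through a sharp front; instead it is
folded into an *effective* heat capacity spread over the mushy temperature
interval [T_m, T_f] (enthalpy method), which is what makes an ordinary
explicit heat-equation stepper handle freezing and thawing.

Units are strict SI internally: J/(kg K), W/(m K), kg/m^3.  Temperatures are
degrees Celsius because every source polynomial is written in Celsius.

The built-in library is loaded from ``data/materials.json`` (documented
schema inside the file); users may load their own library in the same schema
via :func:`MaterialLibrary.from_json`.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

__all__ = [
    "PhaseChangeSpec",
    "Branch",
    "PiecewiseModel",
    "MaterialModel",
    "MaterialLibrary",
    "default_library",
    "density",
    "thermal_conductivity",
    "sensible_heat_capacity",
    "effective_heat_capacity",
    "volumetric_heat_capacity",
    "mushy_weight",
    "mushy_weight_integral",
    "MUSHY_WEIGHTS",
]

# mushy-zone weighting schemes; "t_squared" is the default (normalized so the
# integral over [T_m, T_f] is exactly 1), "printed" is the literal source form
MUSHY_WEIGHTS = ("t_squared", "printed", "uniform", "linear")


@dataclass(frozen=True)
class PhaseChangeSpec:
    """Phase-change constants of one medium.

    T_f is the cryoscopic temperature (ice first forms; upper bound of the
    mushy range), T_m the initial melting temperature (freezable water fully
    frozen; lower bound).  L_eff is the effective latent heat in J/kg -- for
    hydrogel this is L*f_FW*w, for skin/fat the tissue latent heat.  For
    muscle the latent contribution is already embedded in the tabulated heat
    capacity, flagged by ``embedded``.
    """

    T_f: float
    T_m: float
    L_eff: float
    embedded: bool = False

    def __post_init__(self) -> None:
        if not (self.T_m < self.T_f <= 0.0):
            raise ValueError(
                f"require T_m < T_f <= 0 C, got T_m={self.T_m}, T_f={self.T_f}"
            )
        if self.L_eff <= 0.0 and not self.embedded:
            raise ValueError("L_eff must be positive unless flagged embedded")


def _eval_terms(terms: Sequence[tuple[str, Sequence[float]]], T: np.ndarray) -> np.ndarray:
    out = np.zeros_like(T, dtype=float)
    for kind, p in terms:
        if kind == "poly":
            out += np.polynomial.polynomial.polyval(T, np.asarray(p, dtype=float))
        elif kind == "lin_shift":
            a, T0 = p
            out += a * (T - T0)
        elif kind == "inv_diff":
            a, Tref = p
            out += a * (1.0 / T - 1.0 / Tref)
        elif kind == "pow_negT":
            a, q = p
            out += a * np.power(-T, q)
        elif kind == "inv_sq_shift":
            a, c = p
            out += a / (c - T) ** 2
        elif kind == "t_inv_sq_shift":
            a, c = p
            out += a * T / (c - T) ** 2
        else:
            raise ValueError(f"unknown term kind {kind!r}")
    return out


@dataclass(frozen=True)
class Branch:
    """One piecewise branch, valid on [lo, hi) (topmost branch closed)."""

    lo: float
    hi: float
    terms: tuple[tuple[str, tuple[float, ...]], ...]
    scale: float = 1.0

    def __call__(self, T: np.ndarray) -> np.ndarray:
        return self.scale * _eval_terms(self.terms, T)


@dataclass(frozen=True)
class PiecewiseModel:
    """Ordered branches covering a property's valid range with no gaps."""

    branches: tuple[Branch, ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.branches, self.branches[1:]):
            if not math.isclose(a.hi, b.lo, abs_tol=1e-12):
                raise ValueError("piecewise branches must tile the valid range")

    @property
    def lo(self) -> float:
        return self.branches[0].lo

    @property
    def hi(self) -> float:
        return self.branches[-1].hi

    def __call__(self, T: np.ndarray) -> np.ndarray:
        T = np.asarray(T, dtype=float)
        out = np.empty_like(T)
        for k, br in enumerate(self.branches):
            if k == len(self.branches) - 1:
                m = (T >= br.lo) & (T <= br.hi)
            else:
                m = (T >= br.lo) & (T < br.hi)
            if np.any(m):
                out[m] = br(T[m])
        return out


_warned_clamp: set[tuple[str, str]] = set()


def _clamp(name: str, T: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Clamp T to the tabulated range, warning once per material and side.

    Below the coldest tabulated temperature the source data are themselves
    extrapolations, so freezing the property at its boundary value is the
    honest choice.
    """
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError(f"non-finite temperature passed for material {name!r}")
    if np.any(T < lo) and (name, "lo") not in _warned_clamp:
        _warned_clamp.add((name, "lo"))
        warnings.warn(
            f"{name}: temperature below tabulated range ({lo} C); "
            "property clamped to its boundary value",
            stacklevel=3,
        )
    if np.any(T > hi) and (name, "hi") not in _warned_clamp:
        _warned_clamp.add((name, "hi"))
        warnings.warn(
            f"{name}: temperature above tabulated range ({hi} C); "
            "property clamped to its boundary value",
            stacklevel=3,
        )
    return np.clip(T, lo, hi)


def mushy_weight(T, pc: PhaseChangeSpec, kind: str = "t_squared"):
    """Mushy-zone weight g(T) distributing the latent heat over [T_m, T_f].

    All variants are supported on [T_m, T_f] and zero outside.  The default
    ``t_squared`` keeps the 1/T^2 signature of the source expression but is
    normalized so that its integral over the mushy interval is exactly 1;
    ``printed`` is the source expression verbatim (integral 0.986 for
    hydrogel); ``uniform`` and ``linear`` are simple alternatives.
    """
    T = np.asarray(T, dtype=float)
    Tf, Tm = pc.T_f, pc.T_m
    inside = (T >= Tm) & (T <= Tf)
    g = np.zeros_like(T)
    Ti = T[inside]
    if kind == "t_squared":
        g[inside] = (abs(Tf) / Ti**2) / abs(Tf / Tm - 1.0)
    elif kind == "printed":
        g[inside] = np.abs(Tf / Ti**2 - Tf / (Tm * (Tm - Tf)))
    elif kind == "uniform":
        g[inside] = 1.0 / (Tf - Tm)
    elif kind == "linear":
        # ramp rising toward T_f, normalized to unit integral
        g[inside] = 2.0 * (Ti - Tm) / (Tf - Tm) ** 2
    else:
        raise ValueError(f"unknown mushy weight {kind!r}; choose from {MUSHY_WEIGHTS}")
    return g


def mushy_weight_integral(a: float, b: float, pc: PhaseChangeSpec, kind: str = "t_squared") -> float:
    """Exact integral of :func:`mushy_weight` over [a, b] (closed form).

    Used by the solver to build latent-heat-conserving capacity tables.
    """
    Tf, Tm = pc.T_f, pc.T_m
    a = min(max(a, Tm), Tf)
    b = min(max(b, Tm), Tf)
    if b <= a:
        return 0.0
    if kind == "t_squared":
        return abs(Tf) * (1.0 / a - 1.0 / b) / abs(Tf / Tm - 1.0)
    if kind == "printed":
        const = abs(Tf / (Tm * (Tm - Tf)))
        return abs(Tf) * (1.0 / a - 1.0 / b) - const * (b - a)
    if kind == "uniform":
        return (b - a) / (Tf - Tm)
    if kind == "linear":
        return ((b - Tm) ** 2 - (a - Tm) ** 2) / (Tf - Tm) ** 2
    raise ValueError(f"unknown mushy weight {kind!r}")


@dataclass(frozen=True)
class MaterialModel:
    """Thermophysical model of one medium."""

    name: str
    valid_range: tuple[float, float]
    density_model: PiecewiseModel
    conductivity_model: PiecewiseModel
    sensible_cp_model: PiecewiseModel
    phase_change: PhaseChangeSpec | None = None

    # -- scalar/array property evaluation (clamped to the tabulated range) --

    def density(self, T):
        Tc = _clamp(self.name, T, *self.valid_range)
        return self.density_model(Tc)

    def conductivity(self, T):
        Tc = _clamp(self.name, T, *self.valid_range)
        return self.conductivity_model(Tc)

    def sensible_cp(self, T):
        Tc = _clamp(self.name, T, *self.valid_range)
        return self.sensible_cp_model(Tc)

    def effective_cp(self, T, mushy: str = "t_squared"):
        """Sensible capacity plus the latent-heat term inside [T_m, T_f].

        For muscle the tabulated capacity already carries the latent heat
        (``embedded``), so the sensible value is returned unchanged; media
        without phase change (air) likewise.
        """
        Tc = _clamp(self.name, T, *self.valid_range)
        cp = self.sensible_cp_model(Tc)
        pc = self.phase_change
        if pc is None or pc.embedded:
            return cp
        return cp + pc.L_eff * mushy_weight(Tc, pc, mushy)

    def volumetric_heat_capacity(self, T, mushy: str = "t_squared"):
        """rho(T) * Cp_eff(T) in J/(m^3 K)."""
        return self.density(T) * self.effective_cp(T, mushy)


def _branches_from_json(spec: list[dict], default_scale: float = 1.0) -> PiecewiseModel:
    brs = []
    for b in spec:
        lo, hi = b["range"]
        terms = tuple((kind, tuple(p)) for kind, p in b["terms"])
        brs.append(Branch(lo=lo, hi=hi, terms=terms, scale=b.get("scale", default_scale)))
    return PiecewiseModel(tuple(brs))


class MaterialLibrary:
    """Registry of named :class:`MaterialModel` objects."""

    def __init__(self, models: dict[str, MaterialModel]):
        self._models = dict(models)

    def __contains__(self, name: str) -> bool:
        return name in self._models

    def __iter__(self):
        return iter(self._models)

    def ids(self) -> list[str]:
        return list(self._models)

    def get(self, name: str) -> MaterialModel:
        try:
            return self._models[name]
        except KeyError:
            raise KeyError(
                f"unknown material {name!r}; known: {sorted(self._models)}"
            ) from None

    def add(self, model: MaterialModel) -> None:
        self._models[model.name] = model

    @classmethod
    def from_dict(cls, data: dict) -> "MaterialLibrary":
        models = {}
        for name, m in data.items():
            if name.startswith("_"):
                continue
            pc = m.get("phase_change")
            pcs = (
                PhaseChangeSpec(
                    T_f=pc["T_f"], T_m=pc["T_m"], L_eff=pc["L_eff"],
                    embedded=pc.get("embedded", False),
                )
                if pc
                else None
            )
            models[name] = MaterialModel(
                name=name,
                valid_range=tuple(m["valid_range"]),
                density_model=_branches_from_json(m["density"]),
                conductivity_model=_branches_from_json(m["conductivity"]),
                sensible_cp_model=_branches_from_json(m["sensible_cp"]),
                phase_change=pcs,
            )
        return cls(models)

    @classmethod
    def from_json(cls, path) -> "MaterialLibrary":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        raise NotImplementedError(
            "edit data/materials.json (documented schema) to serialize custom libraries"
        )


_default: MaterialLibrary | None = None


def default_library() -> MaterialLibrary:
    """The built-in library (hydrogel_5pct, skin, subcutaneous_fat, muscle, air_effective)."""
    global _default
    if _default is None:
        text = resources.files("cryofront").joinpath("data/materials.json").read_text()
        _default = MaterialLibrary.from_dict(json.loads(text))
    return _default


# -- convenience module-level accessors ------------------------------------

def _model(material: str, library: MaterialLibrary | None) -> MaterialModel:
    return (library or default_library()).get(material)


def density(material: str, T, library: MaterialLibrary | None = None):
    """Density rho(T) in kg/m^3."""
    return _model(material, library).density(T)


def thermal_conductivity(material: str, T, library: MaterialLibrary | None = None):
    """Thermal conductivity k(T) in W/(m K)."""
    return _model(material, library).conductivity(T)


def sensible_heat_capacity(material: str, T, library: MaterialLibrary | None = None):
    """Sensible heat capacity Cp(T) in J/(kg K) (latent-embedded for muscle)."""
    return _model(material, library).sensible_cp(T)


def effective_heat_capacity(material: str, T, library: MaterialLibrary | None = None,
                            mushy: str = "t_squared"):
    """Effective heat capacity Cp_eff(T) in J/(kg K), latent heat included."""
    return _model(material, library).effective_cp(T, mushy)


def volumetric_heat_capacity(material: str, T, library: MaterialLibrary | None = None,
                             mushy: str = "t_squared"):
    """rho(T)*Cp_eff(T) in J/(m^3 K)."""
    return _model(material, library).volumetric_heat_capacity(T, mushy)
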