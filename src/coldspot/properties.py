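"""Composition-based estimation of effective thermophysical properties.

Effective density, specific heat and thermal conductivity of a
multi-component food product are estimated from its proximate composition
(mass fractions of water, protein, fat, carbohydrate and ash) with
standard mixture rules:

* density — mass-fraction harmonic mean, ``rho = 1 / sum(x_i / rho_i)``;
* specific heat — mass-fraction arithmetic mean, ``cp = sum(x_i * cp_i)``;
* conductivity — a ``g``-weighted blend of the volume-fraction parallel
  (arithmetic) and perpendicular/series (harmonic) bounds,
  ``k = g * k_per + (1 - g) * k_par``.

Per-component property constants default to literature values for food
components evaluated at 20 degC; they can be overridden for sensitivity
studies. Properties are treated as temperature-independent constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ComponentPropertyError, CompositionError, ParameterError

__all__ = [
    "COMPONENTS",
    "Composition",
    "ComponentProperties",
    "ThermoProps",
    "CHOI_OKOS_20C",
    "DEFAULT_COMPOSITION",
    "DEFAULT_G",
    "estimate_density",
    "estimate_heat_capacity",
    "volume_fractions",
    "estimate_thermal_conductivity",
    "estimate_all",
]

#: Canonical component ordering used by every array in this module.
COMPONENTS = ("water", "protein", "fat", "carbohydrate", "ash")

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class Composition:
    """Proximate composition as mass fractions summing to one."""

    water: float = 0.0
    protein: float = 0.0
    fat: float = 0.0
    carbohydrate: float = 0.0
    ash: float = 0.0

    def __post_init__(self) -> None:
        x = self.as_array()
        if np.any(x < 0.0) or np.any(x > 1.0):
            raise CompositionError(
                f"mass fractions must lie in [0, 1], got {dict(zip(COMPONENTS, x))}"
            )
        total = float(x.sum())
        if abs(total - 1.0) > _SUM_TOL:
            raise CompositionError(
                f"mass fractions must sum to 1 within {_SUM_TOL}, got {total!r}"
            )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.water, self.protein, self.fat, self.carbohydrate, self.ash],
            dtype=float,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "Composition":
        unknown = set(d) - set(COMPONENTS)
        if unknown:
            raise CompositionError(f"unknown components: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class ComponentProperties:
    """Per-component density, specific heat and thermal conductivity.

    Arrays are aligned with :data:`COMPONENTS`. All entries must be
    strictly positive.
    """

    rho: np.ndarray  # kg/m^3
    cp: np.ndarray  # J/(kg K)
    k: np.ndarray  # W/(m K)

    def __post_init__(self) -> None:
        for name in ("rho", "cp", "k"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(COMPONENTS),):
                raise ComponentPropertyError(
                    f"{name} must have one entry per component "
                    f"({len(COMPONENTS)}), got shape {arr.shape}"
                )
            if np.any(arr <= 0.0) or not np.all(np.isfinite(arr)):
                raise ComponentPropertyError(
                    f"{name} entries must be finite and strictly positive: {arr}"
                )
            object.__setattr__(self, name, arr)

    @classmethod
    def from_dicts(cls, rho: dict, cp: dict, k: dict) -> "ComponentProperties":
        def pack(d: dict, name: str) -> np.ndarray:
            missing = set(COMPONENTS) - set(d)
            if missing:
                raise ComponentPropertyError(f"{name} missing components {sorted(missing)}")
            return np.array([float(d[c]) for c in COMPONENTS])

        return cls(rho=pack(rho, "rho"), cp=pack(cp, "cp"), k=pack(k, "k"))


#: Food-component property constants evaluated at 20 degC from the standard
#: polynomial correlations (order: water, protein, fat, carbohydrate, ash).
CHOI_OKOS_20C = ComponentProperties(
    rho=np.array([995.74, 1319.53, 917.24, 1592.89, 2418.19]),
    cp=np.array([4176.58, 2031.85, 2011.75, 1585.67, 1128.92]),
    k=np.array([0.60366, 0.20164, 0.12543, 0.22743, 0.35648]),
)

#: Default product composition, calibrated once (scripts/calibrate_composition.py)
#: so that the three estimators reproduce the packaged typical property values
#: (1064.5 kg/m^3, 3535.5 J/(kg K), 0.47 W/(m K)). Config-overridable.
DEFAULT_COMPOSITION = Composition(
    water=0.717562,
    protein=0.187851,
    fat=0.052587,
    carbohydrate=0.008,
    ash=0.034,
)

#: Conductivity mixing weight paired with DEFAULT_COMPOSITION (same calibration).
DEFAULT_G = 0.316916


@dataclass(frozen=True)
class ThermoProps:
    """Effective product properties used by the conduction solver."""

    rho: float  # kg/m^3
    cp: float  # J/(kg K)
    k: float  # W/(m K)
    k_par: float | None = None
    k_per: float | None = None
    g: float | None = None

    def __post_init__(self) -> None:
        if min(self.rho, self.cp, self.k) <= 0.0:
            raise ParameterError(
                f"effective properties must be positive: "
                f"rho={self.rho}, cp={self.cp}, k={self.k}"
            )

    @property
    def alpha(self) -> float:
        """Thermal diffusivity k / (rho * cp) in m^2/s."""
        return self.k / (self.rho * self.cp)


def estimate_density(comp: Composition, comp_props: ComponentProperties) -> float:
    """Effective density from the mass-fraction harmonic rule.

    Returns ``1 / sum(x_i / rho_i)`` in kg/m^3; the result is bounded by
    the component densities present in the mixture.
    """
    x = comp.as_array()
    return float(1.0 / np.sum(x / comp_props.rho))


def estimate_heat_capacity(comp: Composition, comp_props: ComponentProperties) -> float:
    """Effective specific heat as the mass-fraction weighted mean, J/(kg K)."""
    return float(np.dot(comp.as_array(), comp_props.cp))


def volume_fractions(comp: Composition, comp_props: ComponentProperties) -> np.ndarray:
    """Per-component volume fractions ``eps_i = (x_i/rho_i) / sum(x_j/rho_j)``."""
    v = comp.as_array() / comp_props.rho
    total = v.sum()
    if total <= 0.0:
        raise CompositionError("total specific volume is zero")
    return v / total


def estimate_thermal_conductivity(
    comp: Composition, comp_props: ComponentProperties, g: float = DEFAULT_G
) -> float:
    """Effective conductivity as a blend of the parallel/series bounds.

    Parameters
    ----------
    g:
        Mixing weight in [0, 1]; ``g = 0`` returns the volume-weighted
        arithmetic (parallel) bound, ``g = 1`` the harmonic
        (perpendicular) bound.
    """
    if not 0.0 <= g <= 1.0:
        raise ParameterError(f"mixing weight g must lie in [0, 1], got {g}")
    eps = volume_fractions(comp, comp_props)
    k_par = float(np.dot(eps, comp_props.k))
    k_per = float(1.0 / np.sum(eps / comp_props.k))
    return g * k_per + (1.0 - g) * k_par


def estimate_all(
    comp: Composition,
    comp_props: ComponentProperties = CHOI_OKOS_20C,
    g: float = DEFAULT_G,
) -> ThermoProps:
    """Evaluate all three mixture rules and return a :class:`ThermoProps`."""
    if not 0.0 <= g <= 1.0:
        raise ParameterError(f"mixing weight g must lie in [0, 1], got {g}")
    eps = volume_fractions(comp, comp_props)
    k_par = float(np.dot(eps, comp_props.k))
    k_per = float(1.0 / np.sum(eps / comp_props.k))
    return ThermoProps(
        rho=estimate_density(comp, comp_props),
        cp=estimate_heat_capacity(comp, comp_props),
        k=g * k_per + (1.0 - g) * k_par,
        k_par=k_par,
        k_per=k_per,
        g=g,
    )
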