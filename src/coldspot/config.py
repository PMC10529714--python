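"""Run configuration: YAML parsing, schema validation and object builders.

A single config drives all commands. The keyword ``default:
hamburgerryg`` loads the packaged scenario (the salted-smoked pork loin
defaults); any explicitly given keys override it. Temperatures may be
given in Kelvin (``*_K`` keys) or Celsius (``*_C`` keys, converted on
load); internally everything is Kelvin. Unknown keys are rejected with
their full key path.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigError
from .properties import (
    CHOI_OKOS_20C,
    Composition,
    ThermoProps,
    estimate_all,
)
from .schedule import DEFAULT_PARAMS, ProcessSchedule
from .solver import Geometry, Grid

__all__ = ["RunConfig", "load_config", "default_config", "dump_config", "config_hash"]

_C_TO_K = 273.15


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    diameter_m: float = Field(gt=0)
    length_m: float = Field(gt=0)

    def build(self) -> Geometry:
        return Geometry.from_full(self.diameter_m, self.length_m)


class DirectProperties(_Strict):
    rho_kg_m3: float = Field(gt=0)
    cp_J_kgK: float = Field(gt=0)
    k_W_mK: float = Field(gt=0)


class CompositionConfig(_Strict):
    water: float = Field(ge=0, le=1)
    protein: float = Field(ge=0, le=1)
    fat: float = Field(ge=0, le=1)
    carbohydrate: float = Field(ge=0, le=1)
    ash: float = Field(ge=0, le=1)


class PropertiesConfig(_Strict):
    direct: Optional[DirectProperties] = None
    composition: Optional[CompositionConfig] = None
    g: float = Field(default=0.5, ge=0, le=1)

    @model_validator(mode="after")
    def _one_route(self):
        if (self.direct is None) == (self.composition is None):
            raise ValueError("give exactly one of 'direct' or 'composition'")
        return self

    def build(self) -> ThermoProps:
        if self.direct is not None:
            return ThermoProps(
                rho=self.direct.rho_kg_m3,
                cp=self.direct.cp_J_kgK,
                k=self.direct.k_W_mK,
            )
        comp = Composition(**self.composition.model_dump())
        return estimate_all(comp, CHOI_OKOS_20C, g=self.g)


class StageConfig(_Strict):
    name: str
    duration_s: float = Field(ge=0)
    T_process_K: float = Field(gt=0)
    h_W_m2K: float = Field(gt=0)


class GridConfig(_Strict):
    nr: int = Field(default=45, ge=4)
    nz: int = Field(default=90, ge=4)

    def build(self) -> Grid:
        return Grid(nr=self.nr, nz=self.nz)


class SolverConfig(_Strict):
    dt_max_s: float = Field(default=30.0, gt=0)
    theta: float = Field(default=0.5, ge=0, le=1)


class ProbeConfig(_Strict):
    r_m: float = Field(default=0.0, ge=0)
    z_m: float = Field(default=0.0, ge=0)


class RunConfig(_Strict):
    """Validated top-level configuration."""

    geometry: GeometryConfig
    properties: PropertiesConfig
    initial_temperature_K: float = Field(gt=0)
    schedule: list[StageConfig]
    grid: GridConfig = GridConfig()
    solver: SolverConfig = SolverConfig()
    probes: list[ProbeConfig] = Field(default_factory=lambda: [ProbeConfig()])
    seed: int = 0

    def build_geometry(self) -> Geometry:
        return self.geometry.build()

    def build_props(self) -> ThermoProps:
        return self.properties.build()

    def build_schedule(self) -> ProcessSchedule:
        return ProcessSchedule.from_stages(
            [s.model_dump() for s in self.schedule]
        )

    def build_grid(self) -> Grid:
        return self.grid.build()

    def probe_points(self) -> tuple[tuple[float, float], ...]:
        return tuple((p.r_m, p.z_m) for p in self.probes)


def _default_dict() -> dict:
    p = DEFAULT_PARAMS
    return {
        "geometry": {"diameter_m": 0.085, "length_m": 0.54},
        "properties": {
            "direct": {"rho_kg_m3": 1064.5, "cp_J_kgK": 3535.5, "k_W_mK": 0.47}
        },
        "initial_temperature_K": 280.65,
        "schedule": [
            {"name": "drying", "duration_s": p["t_d"], "T_process_K": p["T_d"], "h_W_m2K": p["h_d"]},
            {"name": "smoking", "duration_s": p["t_smoke"], "T_process_K": p["T_smoke"], "h_W_m2K": p["h_smoke"]},
            {"name": "transfer1", "duration_s": p["t_trans1"], "T_process_K": p["T_amb"], "h_W_m2K": p["h_amb"]},
            {"name": "steam_cooking", "duration_s": p["t_st"], "T_process_K": p["T_st"], "h_W_m2K": p["h_st"]},
            {"name": "water_cooling", "duration_s": p["t_w"], "T_process_K": p["T_w"], "h_W_m2K": p["h_w"]},
            {"name": "transfer2", "duration_s": p["t_trans2"], "T_process_K": p["T_amb"], "h_W_m2K": p["h_amb"]},
            {"name": "air_cooling", "duration_s": p["t_air"], "T_process_K": p["T_air"], "h_W_m2K": p["h_air"]},
        ],
        "grid": {"nr": 45, "nz": 90},
        "solver": {"dt_max_s": 30.0, "theta": 0.5},
        "probes": [{"r_m": 0.0, "z_m": 0.0}],
        "seed": 0,
    }


def default_config() -> RunConfig:
    """The packaged scenario as a validated RunConfig."""
    return RunConfig.model_validate(_default_dict())


def _convert_celsius(node, path="") -> object:
    """Recursively rewrite ``*_C`` keys to ``*_K`` (value + 273.15)."""
    if isinstance(node, dict):
        out = {}
        for key, val in node.items():
            if isinstance(key, str) and key.endswith("_C"):
                new_key = key[:-2] + "_K"
                if new_key in node:
                    raise ConfigError(
                        f"{path}{key}: both Celsius and Kelvin forms given"
                    )
                out[new_key] = float(val) + _C_TO_K
            else:
                out[key] = _convert_celsius(val, f"{path}{key}.")
        return out
    if isinstance(node, list):
        return [_convert_celsius(v, f"{path}{i}.") for i, v in enumerate(node)]
    return node


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | Path) -> RunConfig:
    """Load, normalize and validate a YAML configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    scenario = raw.pop("default", None)
    if scenario is not None and scenario != "hamburgerryg":
        raise ConfigError(f"unknown default scenario {scenario!r}")
    raw = _convert_celsius(raw)
    data = _deep_merge(_default_dict(), raw) if scenario else raw
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(f"{path}: invalid configuration:\n" + "\n".join(lines)) from exc


def dump_config(cfg: RunConfig) -> str:
    """Serialize a config back to YAML (load -> dump is semantically idempotent)."""
    return yaml.safe_dump(cfg.model_dump(), sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """Stable SHA-256 of the canonical YAML dump (for run manifests)."""
    return hashlib.sha256(dump_config(cfg).encode()).hexdigest()
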