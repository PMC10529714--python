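"""Multistage process schedules: piecewise-constant h(t) and Tp(t).

A schedule is an ordered list of stages, each with a duration, a process
medium temperature and a convective heat-transfer coefficient. Stage
windows are half-open ``[start, end)`` with the final instant of the
whole schedule included, so ``h_at`` and ``Tp_at`` are right-continuous
at interior boundaries and switch at identical times.

The default seven-stage scenario (keyword ``hamburgerryg``) models the
production of a salted-smoked pork loin: drying, smoking, a transfer to
the cooking chamber, steam cooking, water cooling, a second transfer and
air cooling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np

from .errors import DomainError, ScheduleError

__all__ = [
    "ProcessStage",
    "ProcessSchedule",
    "STAGE_NAMES",
    "DEFAULT_PARAMS",
    "build_default_schedule",
    "h_at",
    "Tp_at",
]

STAGE_NAMES = (
    "drying",
    "smoking",
    "transfer1",
    "steam_cooking",
    "water_cooling",
    "transfer2",
    "air_cooling",
)

#: Default process parameters for the packaged scenario. Durations in
#: seconds, temperatures in Kelvin, h in W/(m^2 K). The drying/smoking
#: split of the 12600 s combined stage is an assumption (equal halves)
#: because only the total is specified; both sub-stages share h.
DEFAULT_PARAMS: dict[str, float] = {
    "t_ds": 12600.0,
    "t_d": 6300.0,
    "t_smoke": 6300.0,
    "t_trans1": 1200.0,
    "t_st": 7920.0,
    "t_w": 7200.0,
    "t_trans2": 1200.0,
    "t_air": 54000.0,
    "h_d": 20.0,
    "h_smoke": 20.0,
    "h_amb": 8.0,
    "h_st": 2000.0,
    "h_w": 80.0,
    "h_air": 12.0,
    "T_d": 333.15,
    "T_smoke": 318.15,
    "T_amb": 298.15,
    "T_st": 351.15,
    "T_w": 298.15,
    "T_air": 276.15,
}


@dataclass(frozen=True)
class ProcessStage:
    """One constant-condition process step."""

    name: str
    duration_s: float
    T_process_K: float
    h_W_m2K: float

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise ScheduleError(f"stage {self.name!r}: negative duration {self.duration_s}")
        if self.h_W_m2K <= 0:
            raise ScheduleError(f"stage {self.name!r}: h must be positive, got {self.h_W_m2K}")
        if self.T_process_K <= 0:
            raise ScheduleError(
                f"stage {self.name!r}: temperature must be positive Kelvin, got {self.T_process_K}"
            )


@dataclass(frozen=True)
class ProcessSchedule:
    """Ordered stages plus derived cumulative boundary times.

    Zero-duration stages are retained in ``stages`` for provenance but
    elided from the lookup tables, so boundary times are strictly
    increasing.
    """

    stages: tuple[ProcessStage, ...]

    def __post_init__(self) -> None:
        if not self.stages:
            raise ScheduleError("schedule must contain at least one stage")
        if all(s.duration_s == 0 for s in self.stages):
            raise ScheduleError("schedule has zero total duration")

    @property
    def active_stages(self) -> tuple[ProcessStage, ...]:
        """Stages with strictly positive duration, in order."""
        return tuple(s for s in self.stages if s.duration_s > 0)

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative times ``[0, b_1, ..., total]`` over active stages."""
        durs = [s.duration_s for s in self.active_stages]
        return np.concatenate([[0.0], np.cumsum(durs)])

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration_s for s in self.stages))

    def stage_index_at(self, t: float) -> int:
        """Index into ``active_stages`` of the stage containing time ``t``."""
        b = self.boundaries
        total = b[-1]
        if t < 0 or t > total:
            raise DomainError(f"time {t} outside schedule [0, {total}]")
        if t == total:
            return len(b) - 2
        return int(np.searchsorted(b, t, side="right")) - 1

    def stage_at(self, t: float) -> ProcessStage:
        return self.active_stages[self.stage_index_at(t)]

    def h_at(self, t: float) -> float:
        return self.stage_at(t).h_W_m2K

    def Tp_at(self, t: float) -> float:
        return self.stage_at(t).T_process_K

    def window(self, name: str) -> tuple[float, float]:
        """``(start, end)`` of the first active stage called ``name``."""
        b = self.boundaries
        for i, s in enumerate(self.active_stages):
            if s.name == name:
                return float(b[i]), float(b[i + 1])
        raise ScheduleError(f"no active stage named {name!r}")

    def with_h(self, h_by_stage: Mapping[str, float]) -> "ProcessSchedule":
        """New schedule with h replaced on the named stages."""
        unknown = set(h_by_stage) - {s.name for s in self.stages}
        if unknown:
            raise ScheduleError(f"unknown stage names: {sorted(unknown)}")
        return ProcessSchedule(
            tuple(
                replace(s, h_W_m2K=float(h_by_stage[s.name])) if s.name in h_by_stage else s
                for s in self.stages
            )
        )

    def with_Tp_offsets(self, offset_by_stage: Mapping[str, float]) -> "ProcessSchedule":
        """New schedule with the process temperature shifted on named stages."""
        unknown = set(offset_by_stage) - {s.name for s in self.stages}
        if unknown:
            raise ScheduleError(f"unknown stage names: {sorted(unknown)}")
        return ProcessSchedule(
            tuple(
                replace(s, T_process_K=s.T_process_K + float(offset_by_stage[s.name]))
                if s.name in offset_by_stage
                else s
                for s in self.stages
            )
        )

    @classmethod
    def from_stages(cls, stages: Iterable[ProcessStage | Mapping]) -> "ProcessSchedule":
        out = []
        for s in stages:
            if isinstance(s, ProcessStage):
                out.append(s)
            else:
                out.append(ProcessStage(**s))
        return cls(tuple(out))


def build_default_schedule(params: Mapping[str, float] | None = None) -> ProcessSchedule:
    """Build the packaged seven-stage scenario, optionally overriding parameters.

    ``params`` may override any :data:`DEFAULT_PARAMS` key. If ``t_d`` or
    ``t_smoke`` is overridden without the other, the other is derived from
    ``t_ds``; if both are given they must sum to ``t_ds``.
    """
    p = dict(DEFAULT_PARAMS)
    if params:
        unknown = set(params) - set(DEFAULT_PARAMS)
        if unknown:
            raise ScheduleError(f"unknown schedule parameters: {sorted(unknown)}")
        p.update({k: float(v) for k, v in params.items()})
        if "t_d" in params and "t_smoke" not in params:
            p["t_smoke"] = p["t_ds"] - p["t_d"]
        elif "t_smoke" in params and "t_d" not in params:
            p["t_d"] = p["t_ds"] - p["t_smoke"]
    if abs(p["t_d"] + p["t_smoke"] - p["t_ds"]) > 1e-9:
        raise ScheduleError(
            f"t_d + t_smoke = {p['t_d'] + p['t_smoke']} must equal t_ds = {p['t_ds']}"
        )
    stages = (
        ProcessStage("drying", p["t_d"], p["T_d"], p["h_d"]),
        ProcessStage("smoking", p["t_smoke"], p["T_smoke"], p["h_smoke"]),
        ProcessStage("transfer1", p["t_trans1"], p["T_amb"], p["h_amb"]),
        ProcessStage("steam_cooking", p["t_st"], p["T_st"], p["h_st"]),
        ProcessStage("water_cooling", p["t_w"], p["T_w"], p["h_w"]),
        ProcessStage("transfer2", p["t_trans2"], p["T_amb"], p["h_amb"]),
        ProcessStage("air_cooling", p["t_air"], p["T_air"], p["h_air"]),
    )
    return ProcessSchedule(stages)


def h_at(schedule: ProcessSchedule, t: float) -> float:
    """Heat-transfer coefficient of the stage containing time ``t``."""
    return schedule.h_at(t)


def Tp_at(schedule: ProcessSchedule, t: float) -> float:
    """Process medium temperature of the stage containing time ``t``."""
    return schedule.Tp_at(t)
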