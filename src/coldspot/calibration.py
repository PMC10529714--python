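"""Least-squares estimation of heat-transfer coefficients from probe data.

Unknown stage coefficients (typically the water-cooling and air-cooling
``h``) are estimated by minimizing the sum of squared differences
between the simulated and measured centre-probe series on the 60 s grid.
Residuals are evaluated only from the start of the earliest stage any
free parameter influences: earlier residuals are constant in the
parameters and would only add noise to the objective. The forward
solution up to that point is computed once and cached, so each objective
evaluation integrates the tail of the schedule only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    IdentifiabilityError,
    LoggerDataError,
    ParameterError,
)
from .properties import ThermoProps
from .schedule import ProcessSchedule
from .solver import RECORD_INTERVAL_S, Geometry, Grid, simulate

__all__ = [
    "PARAM_STAGES",
    "DEFAULT_BOUNDS",
    "LoggerDataset",
    "FitResult",
    "ForwardModel",
    "objective",
    "fit_coefficients",
    "read_logger_csv",
    "write_logger_csv",
]

#: Which schedule stages each fittable coefficient acts on.
PARAM_STAGES: dict[str, tuple[str, ...]] = {
    "h_d": ("drying", "smoking"),
    "h_amb": ("transfer1", "transfer2"),
    "h_st": ("steam_cooking",),
    "h_w": ("water_cooling",),
    "h_air": ("air_cooling",),
}

#: Physically plausible bounds, W/(m^2 K).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "h_d": (1.0, 500.0),
    "h_amb": (0.5, 100.0),
    "h_st": (100.0, 10000.0),
    "h_w": (1.0, 500.0),
    "h_air": (0.5, 100.0),
}

_PLAUSIBLE_K = (250.0, 400.0)


@dataclass
class LoggerDataset:
    """One centre-probe temperature series at fixed 60 s cadence."""

    probe_id: str
    times_s: np.ndarray
    temperatures_K: np.ndarray
    pallet: int | None = None
    layer: int | None = None
    position_rz_m: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        y = np.asarray(self.temperatures_K, dtype=float)
        if t.shape != y.shape or t.ndim != 1 or t.size < 2:
            raise LoggerDataError(f"{self.probe_id}: malformed series")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise LoggerDataError(f"{self.probe_id}: timestamps not strictly increasing")
        if np.any(np.abs(dt - RECORD_INTERVAL_S) > 1e-6):
            raise LoggerDataError(
                f"{self.probe_id}: cadence must be {RECORD_INTERVAL_S} s"
            )
        lo, hi = _PLAUSIBLE_K
        if np.any((y < lo) | (y > hi)):
            raise LoggerDataError(
                f"{self.probe_id}: temperatures outside plausible range [{lo}, {hi}] K"
            )
        self.times_s = t
        self.temperatures_K = y


@dataclass
class FitResult:
    """Outcome of a coefficient fit."""

    params: dict[str, float]
    sse_K2: float
    n_evaluations: int
    converged: bool
    bounds: dict[str, tuple[float, float]]
    trace: list[tuple[np.ndarray, float]] = field(default_factory=list)
    message: str = ""

    def best_so_far(self) -> np.ndarray:
        """Monotone envelope of the objective over evaluations."""
        vals = np.array([v for _, v in self.trace])
        return np.minimum.accumulate(vals)


class ForwardModel:
    """Cached forward simulator for objective evaluations.

    The schedule prefix (all stages before the earliest one influenced
    by the free parameters) is integrated once from the uniform initial
    condition; objective evaluations restart from the cached field and
    integrate only the tail with substituted coefficients.
    """

    def __init__(
        self,
        geometry: Geometry,
        props: ThermoProps,
        schedule: ProcessSchedule,
        T0: float,
        free_params: Sequence[str],
        grid: Grid = Grid(),
        dt_max: float = 30.0,
        probe_rz: tuple[float, float] = (0.0, 0.0),
    ):
        if not free_params:
            raise ParameterError("free_params must be nonempty")
        unknown = set(free_params) - set(PARAM_STAGES)
        if unknown:
            raise ParameterError(f"unknown parameters: {sorted(unknown)}")
        self.free_params = tuple(free_params)
        self.geometry, self.props, self.schedule = geometry, props, schedule
        self.T0, self.grid, self.dt_max = float(T0), grid, dt_max
        self.probe_rz = probe_rz

        active_names = [s.name for s in schedule.active_stages]
        touched = [
            active_names.index(st)
            for p in self.free_params
            for st in PARAM_STAGES[p]
            if st in active_names
        ]
        if not touched:
            raise IdentifiabilityError(
                f"none of {self.free_params} acts on an active stage of this schedule"
            )
        self.first_stage_index = min(touched)
        b = schedule.boundaries
        #: Global time at which free parameters start to matter.
        self.t_split = float(b[self.first_stage_index])
        self._prefix_field: np.ndarray | None = None
        if self.first_stage_index > 0:
            prefix = ProcessSchedule(schedule.active_stages[: self.first_stage_index])
            res = simulate(
                geometry, props, prefix, T0, grid,
                probes=(probe_rz,), dt_max=dt_max, store_fields=False,
            )
            self._prefix_field = res.final_field
        #: 60 s evaluation grid of the fit window (absolute times).
        total = schedule.total_duration
        n0 = int(np.ceil(self.t_split / RECORD_INTERVAL_S - 1e-9))
        n1 = int(np.floor(total / RECORD_INTERVAL_S + 1e-9))
        self.window_times = np.arange(n0, n1 + 1) * RECORD_INTERVAL_S

    def predict(self, theta: Mapping[str, float]) -> np.ndarray:
        """Centre-probe series on ``window_times`` for the given coefficients."""
        h_by_stage: dict[str, float] = {}
        for p in self.free_params:
            for st in PARAM_STAGES[p]:
                h_by_stage[st] = float(theta[p])
        sched = self.schedule.with_h(
            {k: v for k, v in h_by_stage.items()
             if k in {s.name for s in self.schedule.stages}}
        )
        tail = ProcessSchedule(sched.active_stages[self.first_stage_index:])
        init = (
            self._prefix_field
            if self._prefix_field is not None
            else np.full((self.grid.nr, self.grid.nz), self.T0)
        )
        res = simulate(
            self.geometry, self.props, tail, init, self.grid,
            probes=(self.probe_rz,), dt_max=self.dt_max, store_fields=False,
        )
        # tail run reports times relative to t_split
        rel = self.window_times - self.t_split
        return np.interp(rel, res.times_s, res.probe_series[0])


def objective(
    theta: Mapping[str, float],
    data: LoggerDataset,
    model: ForwardModel,
) -> float:
    """Sum of squared residuals (K^2) on the fit window."""
    res = _residuals(theta, data, model)
    return float(np.sum(res**2))


def _residuals(theta, data: LoggerDataset, model: ForwardModel) -> np.ndarray:
    pred = model.predict(theta)
    # align measured samples with the window grid
    t0 = model.window_times[0]
    idx = np.round((data.times_s - t0) / RECORD_INTERVAL_S).astype(int)
    keep = (idx >= 0) & (idx < model.window_times.size)
    if not np.any(keep):
        raise IdentifiabilityError(
            f"dataset {data.probe_id!r} has no samples after t = {t0} s, the "
            f"earliest time influenced by {model.free_params}; the requested "
            "parameters cannot be identified from it"
        )
    return pred[idx[keep]] - data.temperatures_K[keep]


def fit_coefficients(
    data: LoggerDataset,
    model: ForwardModel,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    initial_guess: Mapping[str, float] | None = None,
) -> FitResult:
    """Estimate the model's free coefficients from one logger series.

    Uses a bounded trust-region least-squares method. The returned trace
    records every objective evaluation; ``FitResult.best_so_far`` gives
    the non-increasing envelope.
    """
    names = model.free_params
    bnds = {**DEFAULT_BOUNDS, **(bounds or {})}
    for p in names:
        if p not in bnds:
            raise ParameterError(f"no bounds for parameter {p!r}")
    lo = np.array([bnds[p][0] for p in names])
    hi = np.array([bnds[p][1] for p in names])
    if initial_guess is None:
        x0 = np.sqrt(lo * hi)  # geometric midpoint of the bounds
    else:
        x0 = np.array([float(initial_guess[p]) for p in names])
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise ParameterError("initial guess outside bounds")

    # fail fast if the data cannot see the free parameters
    _residuals(dict(zip(names, x0)), data, model)

    trace: list[tuple[np.ndarray, float]] = []

    def fun(x):
        r = _residuals(dict(zip(names, x)), data, model)
        trace.append((x.copy(), float(np.sum(r**2))))
        return r

    sol = least_squares(
        fun, x0, bounds=(lo, hi), method="trf",
        xtol=1e-10, ftol=1e-10, gtol=1e-10, diff_step=1e-3,
    )
    return FitResult(
        params={p: float(v) for p, v in zip(names, sol.x)},
        sse_K2=float(2.0 * sol.cost),
        n_evaluations=len(trace),
        converged=bool(sol.success),
        bounds={p: bnds[p] for p in names},
        trace=trace,
        message=sol.message,
    )


# ---------------------------------------------------------------------------
# logger CSV dialect: two columns, `time_s,temperature_K`

def write_logger_csv(data: LoggerDataset, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"time_s": data.times_s, "temperature_K": data.temperatures_K}
    ).to_csv(path, index=False, float_format="%.17g")
    return path


def read_logger_csv(
    path: str | Path,
    probe_id: str | None = None,
    pallet: int | None = None,
    layer: int | None = None,
) -> LoggerDataset:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["time_s", "temperature_K"]:
        raise LoggerDataError(
            f"{path}: expected header 'time_s,temperature_K', got {list(df.columns)}"
        )
    return LoggerDataset(
        probe_id=probe_id or path.stem,
        times_s=df["time_s"].to_numpy(float),
        temperatures_K=df["temperature_K"].to_numpy(float),
        pallet=pallet,
        layer=layer,
    )
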