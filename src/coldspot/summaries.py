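"""Volume-average / extremum temperature series and validation metrics.

The volume average uses the same finite-volume cell weights as the
solver (cylindrical metric), so it is consistent with the solver's
energy bookkeeping. Cold- and hot-spot locations are the argmin/argmax
node coordinates per recorded time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, ParameterError
from .solver import SimulationResult, _Discretization

__all__ = [
    "SummarySeries",
    "ValidationMetrics",
    "summarize",
    "volume_average",
    "compute_metrics",
]


@dataclass
class SummarySeries:
    """Per-time volume average, extrema and extremum locations."""

    times_s: np.ndarray
    T_avg_K: np.ndarray
    T_min_K: np.ndarray
    T_max_K: np.ndarray
    argmin_rz_m: np.ndarray  # (n_times, 2)
    argmax_rz_m: np.ndarray

    def __post_init__(self) -> None:
        if not (
            np.all(self.T_min_K <= self.T_avg_K + 1e-9)
            and np.all(self.T_avg_K <= self.T_max_K + 1e-9)
        ):
            raise ParameterError("summary violates T_min <= T_avg <= T_max")

    def frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times_s,
                "T_avg_K": self.T_avg_K,
                "T_min_K": self.T_min_K,
                "T_max_K": self.T_max_K,
                "argmin_r_m": self.argmin_rz_m[:, 0],
                "argmin_z_m": self.argmin_rz_m[:, 1],
                "argmax_r_m": self.argmax_rz_m[:, 0],
                "argmax_z_m": self.argmax_rz_m[:, 1],
            }
        )


@dataclass
class ValidationMetrics:
    """R-squared and RMSE of a predicted series against a measured one."""

    r_squared: float
    rmse_K: float
    residuals_K: np.ndarray
    degenerate: bool = False  # measured series constant -> R^2 undefined

    def __post_init__(self) -> None:
        if self.rmse_K < 0:
            raise ParameterError("RMSE cannot be negative")


def volume_average(field: np.ndarray, result: SimulationResult) -> float:
    """Cylindrically weighted mean of one (nr, nz) field."""
    disc = _Discretization(result.geometry, result.grid, result.props)
    return float(np.sum(field * disc.vol) / disc.vol.sum())


def summarize(result: SimulationResult) -> SummarySeries:
    """Reduce a stored-field run to Tavg/Tmin/Tmax series with locations."""
    if result.fields is None or len(result.fields) == 0:
        raise ParameterError(
            "result has no stored fields; rerun simulate with store_fields=True"
        )
    disc = _Discretization(result.geometry, result.grid, result.props)
    w = disc.vol / disc.vol.sum()
    r, z = result.grid.coords(result.geometry)
    fields = result.fields
    flat = fields.reshape(len(fields), -1)
    tavg = flat @ w.ravel()
    imin = np.argmin(flat, axis=1)
    imax = np.argmax(flat, axis=1)
    nz = result.grid.nz
    argmin = np.column_stack([r[imin // nz], z[imin % nz]])
    argmax = np.column_stack([r[imax // nz], z[imax % nz]])
    return SummarySeries(
        times_s=result.times_s,
        T_avg_K=tavg,
        T_min_K=flat[np.arange(len(flat)), imin],
        T_max_K=flat[np.arange(len(flat)), imax],
        argmin_rz_m=argmin,
        argmax_rz_m=argmax,
    )


def compute_metrics(predicted: np.ndarray, measured: np.ndarray) -> ValidationMetrics:
    """RMSE and coefficient of determination about the measured mean.

    ``R^2 = 1 - SS_res / SS_tot`` with ``SS_tot`` taken about the mean of
    the measured series. A constant measured series makes R^2 undefined;
    the result is then flagged ``degenerate`` with ``r_squared = nan``.
    """
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.shape != measured.shape or predicted.ndim != 1:
        raise AlignmentError(
            f"series shapes differ: {predicted.shape} vs {measured.shape}"
        )
    res = predicted - measured
    rmse = float(np.sqrt(np.mean(res**2)))
    ss_tot = float(np.sum((measured - measured.mean()) ** 2))
    if ss_tot == 0.0:
        return ValidationMetrics(float("nan"), rmse, res, degenerate=True)
    r2 = 1.0 - float(np.sum(res**2)) / ss_tot
    return ValidationMetrics(r2, rmse, res)
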