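"""Transient axisymmetric conduction solver with scheduled convective boundaries.

The product is a finite cylinder, reduced by rotational and mid-plane
symmetry to the rectangle ``0 <= r <= R``, ``0 <= z <= L_h`` (axial
coordinate measured from the mid-plane). The heat equation
``rho*cp*dT/dt = div(k grad T)`` is discretized with a conservative
vertex-centred finite-volume scheme on a uniform grid using the
cylindrical metric, so the axis requires no special 1/r treatment and
the discrete energy balance is exact. Convective (Robin) boundary
conditions with the schedule's h(t), Tp(t) act on the lateral surface
``r = R`` and the end face ``z = L_h``; the axis and mid-plane are
adiabatic by symmetry.

Time integration is an implicit theta scheme: each stage restarts the
integrator with a short ramp of small backward-Euler steps (to damp the
boundary-condition jump without over/undershoot) followed by
Crank-Nicolson steps, with every step landing exactly on the 60 s
recording grid and on stage boundaries. Per-stage sparse factorizations
are cached, so long schedules cost one triangular solve per step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .analytic import analytic_finite_cylinder  # re-export: verification oracle
from .errors import DomainError, ParameterError, SolverError
from .properties import ThermoProps
from .schedule import ProcessSchedule

__all__ = [
    "Geometry",
    "Grid",
    "TemperatureField",
    "SimulationResult",
    "simulate",
    "probe",
    "analytic_finite_cylinder",
    "RECORD_INTERVAL_S",
]

#: Cadence of the recorded probe/field series (matches the logger cadence).
RECORD_INTERVAL_S = 60.0

_DEFAULT_RAMP = (1.0, 2.0, 4.0, 8.0, 15.0)


@dataclass(frozen=True)
class Geometry:
    """Half-cylinder: radius and half-length (full product: D = 2R, L = 2*L_h)."""

    radius_m: float
    half_length_m: float

    def __post_init__(self) -> None:
        if self.radius_m <= 0 or self.half_length_m <= 0:
            raise ParameterError(
                f"radius and half-length must be positive, got "
                f"({self.radius_m}, {self.half_length_m})"
            )

    @classmethod
    def from_full(cls, diameter_m: float, length_m: float) -> "Geometry":
        return cls(radius_m=diameter_m / 2.0, half_length_m=length_m / 2.0)


@dataclass(frozen=True)
class Grid:
    """Uniform vertex-centred grid: ``nr`` radial x ``nz`` axial nodes."""

    nr: int = 45
    nz: int = 90

    def __post_init__(self) -> None:
        if self.nr < 4 or self.nz < 4:
            raise ParameterError(f"need at least 4 nodes per axis, got ({self.nr}, {self.nz})")

    def coords(self, geom: Geometry) -> tuple[np.ndarray, np.ndarray]:
        r = np.linspace(0.0, geom.radius_m, self.nr)
        z = np.linspace(0.0, geom.half_length_m, self.nz)
        return r, z


@dataclass(frozen=True)
class TemperatureField:
    """One snapshot of the nodal temperature field (K), shape (nr, nz)."""

    time_s: float
    values: np.ndarray


@dataclass
class StageEnergy:
    """Per-stage energy bookkeeping (Joules, full 3D cylinder)."""

    name: str
    t_start: float
    t_end: float
    boundary_heat_J: float
    internal_energy_change_J: float


@dataclass
class SimulationResult:
    """Output of :func:`simulate`.

    ``times_s`` is the 60 s recording grid (always including t = 0 and
    the final time). ``fields`` holds the field at each recorded time
    when field storage is enabled, shape (n_times, nr, nz). Snapshots are
    stored at every stage boundary plus any requested times.
    """

    geometry: Geometry
    grid: Grid
    props: ThermoProps
    schedule: ProcessSchedule
    T0: float
    times_s: np.ndarray
    fields: np.ndarray | None
    probe_points: tuple[tuple[float, float], ...]
    probe_series: np.ndarray  # (n_probes, n_times)
    snapshots: dict[float, TemperatureField]
    stage_energy: list[StageEnergy]
    step_min_K: float
    step_max_K: float
    final_field: np.ndarray

    def probe_frame(self, index: int = 0):
        import pandas as pd

        return pd.DataFrame(
            {"time_s": self.times_s, "temperature_K": self.probe_series[index]}
        )


class _Discretization:
    """Finite-volume operators on the (r, z) rectangle.

    Cell volumes and face areas carry the full 2*pi cylindrical factor so
    energy totals are physical Joules for the half-cylinder; doubling for
    the mirrored half is left to the caller (symmetry makes it a factor
    of two on both sides of every balance).
    """

    def __init__(self, geom: Geometry, grid: Grid, props: ThermoProps):
        self.geom, self.grid, self.props = geom, grid, props
        nr, nz = grid.nr, grid.nz
        R, Lh = geom.radius_m, geom.half_length_m
        self.dr = R / (nr - 1)
        self.dz = Lh / (nz - 1)
        r = np.linspace(0.0, R, nr)
        # control-volume face radii, clipped to the physical domain
        r_face = np.clip(np.concatenate([[0.0], r[:-1] + self.dr / 2.0, [R]]), 0.0, R)
        self.ar = np.pi * (r_face[1:] ** 2 - r_face[:-1] ** 2)  # radial CV areas (m^2)
        self.az = np.full(nz, self.dz)
        self.az[0] = self.az[-1] = self.dz / 2.0
        self.vol = np.outer(self.ar, self.az)  # (nr, nz) cell volumes, m^3
        self.heat_cap = props.rho * props.cp * self.vol.ravel()  # J/K per cell
        # boundary face areas for Robin terms
        self.area_lateral = 2.0 * np.pi * R * self.az  # per axial node, at r = R
        self.area_end = self.ar.copy()  # per radial node, at z = L_h
        self._r_face_mid = r_face[1:-1]  # interior faces (nr-1 of them)
        self.S = self._conduction_matrix()

    def _conduction_matrix(self) -> sp.csc_matrix:
        """Graph-Laplacian conduction operator S, so C dT/dt = -S T + BC."""
        nr, nz = self.grid.nr, self.grid.nz
        k = self.props.k
        n = nr * nz
        idx = np.arange(n).reshape(nr, nz)
        rows, cols, vals = [], [], []

        def add_pair(a, b, g):
            rows.extend([a, b, a, b])
            cols.extend([a, b, b, a])
            vals.extend([g, g, -g, -g])

        # radial faces between (i, j) and (i+1, j): conductance k*2*pi*r_face*az/dr
        for i in range(nr - 1):
            g_r = k * 2.0 * np.pi * self._r_face_mid[i] * self.az / self.dr
            for j in range(nz):
                add_pair(idx[i, j], idx[i + 1, j], g_r[j])
        # axial faces between (i, j) and (i, j+1): conductance k*ar/dz
        for j in range(nz - 1):
            g_z = k * self.ar / self.dz
            for i in range(nr):
                add_pair(idx[i, j], idx[i, j + 1], g_z[i])
        return sp.csc_matrix(
            sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
        )

    def robin_vector(self, h: float) -> np.ndarray:
        """Per-node boundary conductance h*A (W/K), nonzero on convective faces."""
        nr, nz = self.grid.nr, self.grid.nz
        u = np.zeros((nr, nz))
        u[-1, :] += h * self.area_lateral
        u[:, -1] += h * self.area_end
        return u.ravel()


def _bilinear_weights(geom: Geometry, grid: Grid, r: float, z: float) -> sp.csr_matrix:
    if not (0.0 <= r <= geom.radius_m and 0.0 <= z <= geom.half_length_m):
        raise DomainError(
            f"probe point (r={r}, z={z}) outside domain "
            f"[0, {geom.radius_m}] x [0, {geom.half_length_m}]"
        )
    dr = geom.radius_m / (grid.nr - 1)
    dz = geom.half_length_m / (grid.nz - 1)
    i = min(int(r / dr), grid.nr - 2)
    j = min(int(z / dz), grid.nz - 2)
    fr = r / dr - i
    fz = z / dz - j
    w = np.zeros((grid.nr, grid.nz))
    w[i, j] = (1 - fr) * (1 - fz)
    w[i + 1, j] = fr * (1 - fz)
    w[i, j + 1] = (1 - fr) * fz
    w[i + 1, j + 1] = fr * fz
    return sp.csr_matrix(w.ravel())


def _stage_step_plan(
    t0: float,
    duration: float,
    dt_max: float,
    theta: float,
    ramp: Sequence[float],
    forced: np.ndarray,
) -> list[tuple[float, float]]:
    """Step sizes and theta values for one stage starting at global time t0.

    Steps never cross a recording mark (multiples of RECORD_INTERVAL_S),
    a forced snapshot time, or the stage end. The ramp steps use backward
    Euler (theta = 1) to damp the boundary-condition jump at the stage
    start; subsequent steps use the requested theta.
    """
    eps = 1e-9
    plan: list[tuple[float, float]] = []
    t = t0
    end = t0 + duration
    ramp_left = list(ramp)
    while t < end - eps:
        if ramp_left:
            target, th = ramp_left.pop(0), 1.0
        else:
            target, th = dt_max, theta
        to_mark = RECORD_INTERVAL_S - (t % RECORD_INTERVAL_S)
        if to_mark < eps:
            to_mark = RECORD_INTERVAL_S
        dt = min(target, to_mark, end - t)
        ahead = forced[(forced > t + eps) & (forced < t + dt - eps)]
        if ahead.size:
            dt = ahead[0] - t
        if dt <= eps:
            raise SolverError(f"step size collapsed to {dt} at t = {t}")
        plan.append((dt, th))
        t += dt
    return plan


def simulate(
    geometry: Geometry,
    props: ThermoProps,
    schedule: ProcessSchedule,
    T0: float,
    grid: Grid = Grid(),
    probes: Sequence[tuple[float, float]] = ((0.0, 0.0),),
    snapshot_times: Sequence[float] = (),
    dt_max: float = 30.0,
    theta: float = 0.5,
    ramp: Sequence[float] = _DEFAULT_RAMP,
    store_fields: bool = True,
) -> SimulationResult:
    """Run the full scheduled transient and record 60 s series.

    Parameters
    ----------
    T0:
        Initial temperature (K): a scalar for a uniform field, or an
        ``(nr, nz)`` array to restart from a previously computed field
        (used by the calibration cache).
    probes:
        ``(r, z)`` points (m, mid-plane coordinates) sampled by bilinear
        interpolation at the 60 s cadence.
    snapshot_times:
        Extra times at which the full field is stored; stage boundaries
        are always included.
    dt_max, theta, ramp:
        Time-step ceiling (s), implicit weighting for post-ramp steps
        (0.5 = Crank-Nicolson) and the backward-Euler ramp applied after
        each stage restart.
    store_fields:
        When True (default) the field at every recorded time is kept
        (needed by volume summaries); calibration loops switch it off.
    """
    if not 0.0 <= theta <= 1.0:
        raise ParameterError(f"theta must lie in [0, 1], got {theta}")
    disc = _Discretization(geometry, grid, props)
    n = grid.nr * grid.nz
    if np.ndim(T0) == 0:
        if T0 <= 0:
            raise ParameterError(f"initial temperature must be positive Kelvin, got {T0}")
        T = np.full(n, float(T0))
    else:
        T = np.asarray(T0, dtype=float)
        if T.shape != (grid.nr, grid.nz):
            raise ParameterError(
                f"initial field shape {T.shape} does not match grid ({grid.nr}, {grid.nz})"
            )
        if np.any(T <= 0):
            raise ParameterError("initial field must be positive Kelvin everywhere")
        T = T.ravel().copy()

    probe_points = tuple((float(r), float(z)) for r, z in probes)
    W = sp.vstack([_bilinear_weights(geometry, grid, r, z) for r, z in probe_points])

    forced = np.unique(np.asarray(sorted(snapshot_times), dtype=float))
    total = schedule.total_duration
    if forced.size and (forced.min() < 0 or forced.max() > total):
        raise DomainError(f"snapshot times must lie in [0, {total}]")

    rec_times = [0.0]
    rec_fields = [T.copy().reshape(grid.nr, grid.nz)] if store_fields else None
    rec_probes = [np.asarray(W @ T).ravel()]
    snapshots: dict[float, TemperatureField] = {
        0.0: TemperatureField(0.0, T.copy().reshape(grid.nr, grid.nz))
    }
    stage_energy: list[StageEnergy] = []
    t_min, t_max = float(T.min()), float(T.max())

    eps = 1e-9
    lu_cache: dict[tuple[int, float, float], object] = {}

    boundaries = schedule.boundaries
    active = schedule.active_stages
    t = 0.0
    for si, stage in enumerate(active):
        h, Tp = stage.h_W_m2K, stage.T_process_K
        u = disc.robin_vector(h)
        b = u * Tp
        A_op = disc.S + sp.diags(u)
        E_start = float(np.dot(disc.heat_cap, T))
        Q_in = 0.0
        plan = _stage_step_plan(t, stage.duration_s, dt_max, theta, ramp, forced)
        for dt, th in plan:
            key = (si, dt, th)
            if key not in lu_cache:
                M = sp.diags(disc.heat_cap / dt)
                lu_cache[key] = (
                    splu(sp.csc_matrix(M + th * A_op)),
                    sp.csc_matrix(M - (1.0 - th) * A_op),
                )
            lu, B = lu_cache[key]
            rhs = B @ T + b
            T_new = lu.solve(rhs)
            if not np.all(np.isfinite(T_new)):
                raise SolverError(
                    f"non-finite temperatures in stage {stage.name!r} at t = {t}"
                )
            T_mix = th * T_new + (1.0 - th) * T
            Q_in += dt * float(np.dot(u, Tp - T_mix))
            T = T_new
            t += dt
            t_min = min(t_min, float(T.min()))
            t_max = max(t_max, float(T.max()))
            on_mark = (t % RECORD_INTERVAL_S) < eps or (
                RECORD_INTERVAL_S - (t % RECORD_INTERVAL_S)
            ) < eps
            if on_mark:
                rec_times.append(round(t / RECORD_INTERVAL_S) * RECORD_INTERVAL_S)
                rec_probes.append(np.asarray(W @ T).ravel())
                if store_fields:
                    rec_fields.append(T.copy().reshape(grid.nr, grid.nz))
            hit_forced = forced[np.abs(forced - t) < eps]
            if hit_forced.size:
                ts = float(hit_forced[0])
                snapshots[ts] = TemperatureField(ts, T.copy().reshape(grid.nr, grid.nz))
        t = float(boundaries[si + 1])  # re-anchor to kill float drift
        snapshots[t] = TemperatureField(t, T.copy().reshape(grid.nr, grid.nz))
        stage_energy.append(
            StageEnergy(
                name=stage.name,
                t_start=float(boundaries[si]),
                t_end=t,
                boundary_heat_J=Q_in,
                internal_energy_change_J=float(np.dot(disc.heat_cap, T)) - E_start,
            )
        )

    if abs(rec_times[-1] - t) > eps:  # final time not on the 60 s grid
        rec_times.append(t)
        rec_probes.append(np.asarray(W @ T).ravel())
        if store_fields:
            rec_fields.append(T.copy().reshape(grid.nr, grid.nz))

    times = np.asarray(rec_times)
    return SimulationResult(
        geometry=geometry,
        grid=grid,
        props=props,
        schedule=schedule,
        T0=float(np.mean(T0)),
        times_s=times,
        fields=np.asarray(rec_fields) if store_fields else None,
        probe_points=probe_points,
        probe_series=np.asarray(rec_probes).T,
        snapshots=snapshots,
        stage_energy=stage_energy,
        step_min_K=t_min,
        step_max_K=t_max,
        final_field=T.reshape(grid.nr, grid.nz),
    )


def probe(result: SimulationResult, r: float, z: float) -> np.ndarray:
    """Post-hoc 60 s temperature series at ``(r, z)`` by bilinear interpolation.

    Requires the run to have stored fields; points that were passed as
    ``probes`` to :func:`simulate` are available either way through
    ``result.probe_series``.
    """
    for i, (pr, pz) in enumerate(result.probe_points):
        if abs(pr - r) < 1e-12 and abs(pz - z) < 1e-12:
            return result.probe_series[i]
    if result.fields is None:
        raise SolverError(
            "fields were not stored for this run; request the point via "
            "simulate(..., probes=...) or rerun with store_fields=True"
        )
    w = _bilinear_weights(result.geometry, result.grid, r, z)
    flat = result.fields.reshape(result.fields.shape[0], -1)
    return np.asarray(flat @ w.toarray().ravel())
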