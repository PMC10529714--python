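"""Synthetic logger bundles emulating the industrial probe experiment.

Sixteen centre-of-product probes are laid out on 4 pallets x 4 layers.
Positional structure is injected through the process schedule: the
water-cooling medium is colder at the top of a pallet than at the bottom
(the water heats up as it flows down), modelled as a per-layer offset on
the water temperature, linear in layer index between +dT (bottom layer)
and -dT (top layer); pallet position inside the drying-smoking chamber
is modelled as a uniform per-pallet offset on the drying and smoking
temperatures. Additive iid Gaussian noise emulates logger error. All
randomness is driven by a single seed, so identical inputs reproduce
identical bundles byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .calibration import LoggerDataset, read_logger_csv, write_logger_csv
from .errors import ParameterError
from .properties import ThermoProps
from .schedule import ProcessSchedule
from .solver import Geometry, Grid, simulate

__all__ = [
    "ProbeLayout",
    "PerturbationModel",
    "default_layout",
    "generate_loggers",
    "write_fixture_bundle",
    "read_fixture_bundle",
]

#: Probe id -> (pallet, layer) of the emulated experiment; layers are
#: counted bottom (1) to top (10), probes sit on layers 3, 5, 7 and 10.
_DEFAULT_PLACEMENT: dict[str, tuple[int, int]] = {
    "T12": (1, 10), "T10": (1, 7), "T11": (1, 5), "T2": (1, 3),
    "T3": (2, 10), "T5": (2, 7), "T16": (2, 5), "T15": (2, 3),
    "T7": (3, 10), "T6": (3, 7), "T14": (3, 5), "T8": (3, 3),
    "T13": (4, 10), "T4": (4, 7), "T1": (4, 5), "T9": (4, 3),
}

#: The probe used for calibration (the others validate).
CALIBRATION_PROBE = "T11"

_LAYER_BOTTOM, _LAYER_TOP = 3, 10


@dataclass(frozen=True)
class ProbeLayout:
    """Assignment of probe ids to (pallet, layer) positions."""

    placement: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        pallets: dict[int, set[int]] = {}
        for pid, (pallet, layer) in self.placement.items():
            if not (_LAYER_BOTTOM <= layer <= _LAYER_TOP):
                raise ParameterError(
                    f"probe {pid}: layer {layer} outside [{_LAYER_BOTTOM}, {_LAYER_TOP}]"
                )
            pallets.setdefault(pallet, set()).add(layer)
        if len(self.placement) != 16 or len(pallets) != 4:
            raise ParameterError("layout must place 16 probes on 4 pallets")
        for pallet, layers in pallets.items():
            if layers != {3, 5, 7, 10}:
                raise ParameterError(
                    f"pallet {pallet} must cover layers 3, 5, 7, 10, got {sorted(layers)}"
                )


def default_layout() -> ProbeLayout:
    return ProbeLayout(dict(_DEFAULT_PLACEMENT))


@dataclass(frozen=True)
class PerturbationModel:
    """Positional offsets and measurement noise for a synthetic bundle."""

    delta_Tw_K: float = 5.0
    pallet_offsets_K: Mapping[int, float] = field(
        default_factory=lambda: {1: 2.0, 2: -2.0, 3: 1.0, 4: -1.0}
    )
    sigma_K: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_K < 0:
            raise ParameterError(f"noise sigma must be >= 0, got {self.sigma_K}")
        if abs(self.delta_Tw_K) > 20.0:
            raise ParameterError("water-temperature offset beyond plausible range")

    def water_offset(self, layer: int) -> float:
        """Linear in layer: +dT at the bottom layer, -dT at the top."""
        mid = (_LAYER_BOTTOM + _LAYER_TOP) / 2.0
        half = (_LAYER_TOP - _LAYER_BOTTOM) / 2.0
        return self.delta_Tw_K * (mid - layer) / half


def generate_loggers(
    layout: ProbeLayout,
    geometry: Geometry,
    props: ThermoProps,
    schedule: ProcessSchedule,
    T0: float,
    perturbation: PerturbationModel,
    grid: Grid = Grid(),
    dt_max: float = 30.0,
) -> tuple[list[LoggerDataset], dict]:
    """Simulate all probes and return labelled noisy series plus ground truth.

    Each probe's forward run perturbs the water-cooling temperature by
    its layer offset and the drying/smoking temperatures by its pallet
    offset; the centre is sampled at 60 s and iid N(0, sigma^2) noise is
    added from a per-probe child stream of the bundle seed.

    Returns ``(datasets, truth)`` where ``truth`` records the generating
    coefficients and offsets for parameter-recovery tests.
    """
    rng = np.random.default_rng(perturbation.seed)
    stage_names = {s.name for s in schedule.stages}
    datasets: list[LoggerDataset] = []
    truth: dict = {
        "seed": perturbation.seed,
        "sigma_K": perturbation.sigma_K,
        "delta_Tw_K": perturbation.delta_Tw_K,
        "pallet_offsets_K": {str(k): v for k, v in perturbation.pallet_offsets_K.items()},
        "h_true": {s.name: s.h_W_m2K for s in schedule.active_stages},
        "probes": {},
    }
    # deterministic iteration order + one child stream per probe
    ordered = sorted(layout.placement.items())
    streams = rng.spawn(len(ordered))
    cache: dict[tuple[float, float], np.ndarray] = {}
    for (pid, (pallet, layer)), stream in zip(ordered, streams):
        w_off = perturbation.water_offset(layer)
        p_off = float(perturbation.pallet_offsets_K.get(pallet, 0.0))
        offsets = {}
        if "water_cooling" in stage_names and w_off:
            offsets["water_cooling"] = w_off
        for st in ("drying", "smoking"):
            if st in stage_names and p_off:
                offsets[st] = p_off
        key = (w_off, p_off)
        if key not in cache:
            sched_i = schedule.with_Tp_offsets(offsets) if offsets else schedule
            res = simulate(
                geometry, props, sched_i, T0, grid,
                probes=((0.0, 0.0),), dt_max=dt_max, store_fields=False,
            )
            cache[key] = (res.times_s, res.probe_series[0])
        times, clean = cache[key]
        noise = stream.normal(0.0, perturbation.sigma_K, size=clean.shape)
        datasets.append(
            LoggerDataset(
                probe_id=pid,
                times_s=times.copy(),
                temperatures_K=clean + noise,
                pallet=pallet,
                layer=layer,
            )
        )
        truth["probes"][pid] = {
            "pallet": pallet,
            "layer": layer,
            "water_offset_K": w_off,
            "pallet_offset_K": p_off,
        }
    return datasets, truth


def write_fixture_bundle(
    datasets: Sequence[LoggerDataset],
    truth: dict,
    out_dir: str | Path,
    config_text: str | None = None,
) -> list[Path]:
    """Write logger CSVs + metadata (+ generating config) and return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []
    for ds in datasets:
        manifest.append(write_logger_csv(ds, out / f"{ds.probe_id}.csv"))
    meta = dict(truth)
    meta["files"] = {ds.probe_id: f"{ds.probe_id}.csv" for ds in datasets}
    meta_path = out / "metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    manifest.append(meta_path)
    if config_text is not None:
        cfg_path = out / "config.yaml"
        cfg_path.write_text(config_text)
        manifest.append(cfg_path)
    return manifest


def read_fixture_bundle(bundle_dir: str | Path) -> tuple[list[LoggerDataset], dict]:
    """Inverse of :func:`write_fixture_bundle` (lossless round trip)."""
    bundle = Path(bundle_dir)
    meta = json.loads((bundle / "metadata.json").read_text())
    datasets = []
    for pid, fname in sorted(meta["files"].items()):
        info = meta["probes"][pid]
        datasets.append(
            read_logger_csv(
                bundle / fname, probe_id=pid,
                pallet=info["pallet"], layer=info["layer"],
            )
        )
    return datasets, meta
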