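import numpy as np
import pytest

from coldspot.calibration import ForwardModel, fit_coefficients
from coldspot.errors import ParameterError
from coldspot.schedule import build_default_schedule
from coldspot.solver import simulate
from coldspot.synthetic_data import (
    CALIBRATION_PROBE,
    PerturbationModel,
    ProbeLayout,
    default_layout,
    generate_loggers,
    read_fixture_bundle,
    write_fixture_bundle,
)

from conftest import COARSE_GRID, DEFAULT_GEOM, DEFAULT_PROPS, T0_DEFAULT


def gen(pert, grid=COARSE_GRID, dt_max=60.0):
    return generate_loggers(
        default_layout(), DEFAULT_GEOM, DEFAULT_PROPS, build_default_schedule(),
        T0_DEFAULT, pert, grid=grid, dt_max=dt_max,
    )


class TestLayout:
    def test_default_layout_valid(self):
        layout = default_layout()
        pallets = {}
        for pid, (pallet, layer) in layout.placement.items():
            pallets.setdefault(pallet, []).append(layer)
        assert len(layout.placement) == 16
        for layers in pallets.values():
            assert sorted(layers) == [3, 5, 7, 10]
        assert layout.placement[CALIBRATION_PROBE] == (1, 5)

    def test_invalid_layout_rejected(self):
        bad = dict(default_layout().placement)
        bad["T12"] = (1, 5)  # duplicate layer on pallet 1, layer 10 missing
        with pytest.raises(ParameterError):
            ProbeLayout(bad)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ParameterError):
            PerturbationModel(sigma_K=-0.1)


class TestOffsets:
    def test_layer_offset_shape(self):
        pert = PerturbationModel(delta_Tw_K=5.0, seed=0)
        assert pert.water_offset(3) == pytest.approx(5.0)
        assert pert.water_offset(10) == pytest.approx(-5.0)
        # interior layers interpolate linearly
        assert pert.water_offset(5) == pytest.approx(5.0 * 1.5 / 3.5)
        assert pert.water_offset(7) == pytest.approx(-5.0 * 0.5 / 3.5)


class TestGenerate:
    def test_zero_noise_zero_offsets_identical(self):
        pert = PerturbationModel(
            delta_Tw_K=0.0, pallet_offsets_K={}, sigma_K=0.0, seed=0
        )
        datasets, truth = gen(pert)
        ref = simulate(
            DEFAULT_GEOM, DEFAULT_PROPS, build_default_schedule(), T0_DEFAULT,
            COARSE_GRID, dt_max=60.0, store_fields=False,
        )
        for ds in datasets:
            assert np.array_equal(ds.temperatures_K, ref.probe_series[0])
        assert len(datasets) == 16
        assert truth["h_true"]["water_cooling"] == 80.0

    def test_seeded_determinism(self):
        pert = PerturbationModel(seed=42)
        d1, _ = gen(pert)
        d2, _ = gen(pert)
        for a, b in zip(d1, d2):
            assert a.probe_id == b.probe_id
            assert np.array_equal(a.temperatures_K, b.temperatures_K)

    def test_different_seed_differs(self):
        d1, _ = gen(PerturbationModel(seed=1))
        d2, _ = gen(PerturbationModel(seed=2))
        assert not np.array_equal(d1[0].temperatures_K, d2[0].temperatures_K)

    def test_top_layer_cooler_during_water_cooling(self):
        """dTw = 5 K: top-layer series strictly below bottom-layer after 600 s."""
        pert = PerturbationModel(
            delta_Tw_K=5.0, pallet_offsets_K={}, sigma_K=0.0, seed=0
        )
        datasets, _ = gen(pert)
        by_id = {d.probe_id: d for d in datasets}
        top, bottom = by_id["T12"], by_id["T2"]  # pallet 1, layers 10 and 3
        sched = build_default_schedule()
        a, b = sched.window("water_cooling")
        m = (top.times_s >= a + 600.0) & (top.times_s <= b)
        assert np.all(top.temperatures_K[m] < bottom.temperatures_K[m])

    def test_noise_rmse_matches_sigma(self):
        clean_pert = PerturbationModel(
            delta_Tw_K=0.0, pallet_offsets_K={}, sigma_K=0.0, seed=5
        )
        noisy_pert = PerturbationModel(
            delta_Tw_K=0.0, pallet_offsets_K={}, sigma_K=0.5, seed=5
        )
        clean, _ = gen(clean_pert)
        noisy, _ = gen(noisy_pert)
        for c, n in zip(clean, noisy):
            rmse = np.sqrt(np.mean((n.temperatures_K - c.temperatures_K) ** 2))
            assert rmse == pytest.approx(0.5, rel=0.10)  # 1403 samples

    def test_bundle_average_approaches_clean(self):
        pert = PerturbationModel(
            delta_Tw_K=0.0, pallet_offsets_K={}, sigma_K=0.25, seed=9
        )
        datasets, _ = gen(pert)
        ref = simulate(
            DEFAULT_GEOM, DEFAULT_PROPS, build_default_schedule(), T0_DEFAULT,
            COARSE_GRID, dt_max=60.0, store_fields=False,
        )
        avg = np.mean([d.temperatures_K for d in datasets], axis=0)
        # mean of 16 iid-noise series: std ~ sigma/4
        assert np.max(np.abs(avg - ref.probe_series[0])) < 0.25  # ~4 sigma/4


class TestBundleIO:
    def test_manifest_and_roundtrip(self, tmp_path):
        pert = PerturbationModel(sigma_K=0.3, seed=11)
        datasets, truth = gen(pert)
        manifest = write_fixture_bundle(datasets, truth, tmp_path, config_text="x: 1\n")
        assert len(manifest) == 18  # 16 loggers + metadata + config
        back, meta = read_fixture_bundle(tmp_path)
        by_id = {d.probe_id: d for d in back}
        rng = np.random.default_rng(0)
        for ds in rng.choice(datasets, size=3, replace=False):
            got = by_id[ds.probe_id]
            assert np.array_equal(got.times_s, ds.times_s)
            assert np.array_equal(got.temperatures_K, ds.temperatures_K)
            assert got.pallet == ds.pallet and got.layer == ds.layer
        assert meta["sigma_K"] == 0.3

    def test_regeneration_reproduces_files(self, tmp_path):
        pert = PerturbationModel(sigma_K=0.3, seed=11)
        d1, t1 = gen(pert)
        d2, t2 = gen(pert)
        p1, p2 = tmp_path / "a", tmp_path / "b"
        write_fixture_bundle(d1, t1, p1)
        write_fixture_bundle(d2, t2, p2)
        for f1 in sorted(p1.iterdir()):
            assert f1.read_bytes() == (p2 / f1.name).read_bytes()


class TestRecoveryClosure:
    def test_fit_recovers_generating_coefficients(self):
        """Noise-only bundle: the calibration probe recovers h_w, h_air."""
        pert = PerturbationModel(
            delta_Tw_K=0.0, pallet_offsets_K={}, sigma_K=0.5, seed=21
        )
        from conftest import FIT_GRID

        datasets, truth = generate_loggers(
            default_layout(), DEFAULT_GEOM, DEFAULT_PROPS, build_default_schedule(),
            T0_DEFAULT, pert, grid=FIT_GRID, dt_max=60.0,
        )
        t11 = next(d for d in datasets if d.probe_id == CALIBRATION_PROBE)
        model = ForwardModel(
            DEFAULT_GEOM, DEFAULT_PROPS, build_default_schedule(), T0_DEFAULT,
            ["h_w", "h_air"], grid=FIT_GRID, dt_max=60.0,
        )
        fit = fit_coefficients(t11, model, initial_guess={"h_w": 40.0, "h_air": 6.0})
        assert fit.converged
        assert fit.params["h_w"] == pytest.approx(truth["h_true"]["water_cooling"], rel=0.05)
        assert fit.params["h_air"] == pytest.approx(truth["h_true"]["air_cooling"], rel=0.05)
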