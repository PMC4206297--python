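import numpy as np
import pytest

from irifcyto import (
    CrowdedFieldError,
    SimulationConfig,
    apply_noise,
    simulate_field,
)


class TestGenerativeModels:
    def test_unirradiated_noise_free_is_constant_diffuse(self, noise_free_config):
        fov, truth = simulate_field(noise_free_config)
        in_nucleus = (truth.nucleus_label_map > 0) & ~truth.nucleolus_mask
        assert np.all(fov.target[in_nucleus] == 1000 + 50)
        assert np.all(fov.target[truth.nucleus_label_map == 0] == 50)

    def test_total_degradation_limit(self):
        cfg = SimulationConfig(model="degradation", survival_fraction=0.0, noise=False, seed=4)
        fov, truth = simulate_field(cfg)
        foci = truth.focus_label_map > 0
        nucleoplasm = (truth.nucleus_label_map > 0) & ~foci & ~truth.nucleolus_mask
        assert np.all(fov.target[nucleoplasm] == 50)       # background only
        assert np.all(fov.target[foci] == 1050)            # protected at pre-IR level

    def test_degradation_scaling_exact(self):
        cfg = SimulationConfig(model="degradation", survival_fraction=0.37, noise=False, seed=4)
        _, truth = simulate_field(cfg)
        foci = truth.focus_label_map > 0
        nucleoplasm = (truth.nucleus_label_map > 0) & ~foci & ~truth.nucleolus_mask
        np.testing.assert_allclose(truth.true_signal[nucleoplasm] / 1000.0, 0.37)
        np.testing.assert_allclose(truth.true_signal[foci] / 1000.0, 1.0)

    @pytest.mark.parametrize("r", [0.0, 0.3, 0.7, 1.0])
    def test_recruitment_conserves_per_nucleus_signal(self, r):
        """Direct summation over the true-signal grid: integrated signal per
        nucleus equals the unirradiated value for the same geometry."""
        cfg = SimulationConfig(model="recruitment", recruited_fraction=r, noise=False, seed=9)
        _, truth = simulate_field(cfg)
        for k in truth.per_nucleus_truth["nucleus_id"]:
            region = truth.nucleus_label_map == k
            signal_area = region.sum() - (region & truth.nucleolus_mask).sum()
            expected = 1000.0 * signal_area
            assert abs(truth.true_signal[region].sum() - expected) < 1e-6 * expected

    def test_quantized_recruitment_field_conserves_within_rounding(self):
        # geometry chosen so focus values stay below the 12-bit ceiling,
        # where quantization is the only deviation from exact conservation
        cfg = SimulationConfig(model="recruitment", recruited_fraction=0.1,
                               foci_per_nucleus=(12, 12), focus_radius=(2.5, 2.5),
                               noise=False, seed=9)
        fov, truth = simulate_field(cfg)
        assert truth.true_signal.max() + 50 < 4095
        for k in truth.per_nucleus_truth["nucleus_id"]:
            region = truth.nucleus_label_map == k
            total = int(fov.target[region].sum()) - 50 * int(region.sum())
            signal_area = region.sum() - (region & truth.nucleolus_mask).sum()
            assert abs(total - 1000 * signal_area) <= region.sum()  # +/-1 per pixel


class TestGeometryInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_foci_inside_parent_and_disjoint_from_nucleoli(self, seed):
        cfg = SimulationConfig(
            model="degradation", nucleoli_per_nucleus=(1, 3), seed=seed
        )
        _, truth = simulate_field(cfg)
        foci = truth.focus_label_map > 0
        assert np.all(truth.nucleus_label_map[foci] > 0)
        assert not np.any(foci & truth.nucleolus_mask)
        assert np.all(truth.true_signal >= 0)
        # focus labels key back to the correct parent nucleus
        for fid, parent in truth.focus_parent.items():
            px = truth.focus_label_map == fid
            assert np.all(truth.nucleus_label_map[px] == parent)

    def test_label_maps_consistent_with_truth_table(self):
        cfg = SimulationConfig(model="degradation", seed=3)
        _, truth = simulate_field(cfg)
        for row in truth.per_nucleus_truth.itertuples():
            region = truth.nucleus_label_map == row.nucleus_id
            assert int(region.sum()) == row.area
            in_region_foci = set(np.unique(truth.focus_label_map[region])) - {0}
            assert len(in_region_foci) == row.focus_count
            assert int(((truth.focus_label_map > 0) & region).sum()) == row.focus_area

    def test_nucleoli_are_dark_in_target(self):
        cfg = SimulationConfig(
            model="unirradiated", nucleoli_per_nucleus=(2, 2), noise=False, seed=6
        )
        fov, truth = simulate_field(cfg)
        assert truth.nucleolus_mask.any()
        assert np.all(fov.target[truth.nucleolus_mask] == 50)

    def test_crowded_field_raises(self):
        cfg = SimulationConfig(model="unirradiated", field_shape=(96, 96), n_nuclei=20)
        with pytest.raises(CrowdedFieldError, match="crowded|too small"):
            simulate_field(cfg)


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"survival_fraction": 1.2},
            {"recruited_fraction": -0.1},
            {"nucleus_radius": (0.0, 5.0)},
            {"focus_radius": (3.0, 2.0)},
            {"n_nuclei": 0},
            {"read_noise_sd": -1.0},
            {"model": "ablation"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            simulate_field(SimulationConfig(**kwargs))


class TestNoiseModel:
    def test_zero_everything_gives_zero_image(self):
        out = apply_noise(np.zeros((8, 8)), background=0, read_noise_sd=0, seed=1)
        assert np.all(out == 0)

    def test_poisson_moments(self):
        """Sample mean of a constant field within 3 sd/sqrt(N) of signal+background."""
        n = 512
        out = apply_noise(np.full((n, n), 1000.0), background=50, read_noise_sd=5, seed=2)
        sd = np.sqrt(1050 + 25)
        assert abs(out.mean() - 1050) < 3 * sd / n

    def test_noise_is_seeded(self):
        a = apply_noise(np.full((32, 32), 500.0), 50, 5, seed=7)
        b = apply_noise(np.full((32, 32), 500.0), 50, 5, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            apply_noise(np.full((4, 4), -1.0), 0, 0, seed=1)
        with pytest.raises(ValueError):
            apply_noise(np.zeros((4, 4)), 0, -2.0, seed=1)

    def test_clipped_to_12bit(self):
        out = apply_noise(np.full((16, 16), 1e6), 0, 0, seed=1)
        assert out.max() == 4095


def test_simulation_fully_reproducible():
    cfg = SimulationConfig(model="recruitment", seed=123)
    fov_a, truth_a = simulate_field(cfg)
    fov_b, truth_b = simulate_field(cfg)
    np.testing.assert_array_equal(fov_a.target, fov_b.target)
    np.testing.assert_array_equal(fov_a.dapi, fov_b.dapi)
    np.testing.assert_array_equal(truth_a.nucleus_label_map, truth_b.nucleus_label_map)
    assert truth_a.per_nucleus_truth.equals(truth_b.per_nucleus_truth)
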