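import numpy as np
import pytest

from irifcyto import (
    FociParams,
    SimulationConfig,
    analyze_nuclei,
    detect_foci,
    match_to_truth,
    normalized_foci_intensity,
    nucleus_intensity_record,
    reference_diffuse_mean,
    segment_nuclei,
    simulate_field,
    summarize_normalized,
)


def _per_nucleus_crops(fov, mask):
    for row in mask.regions.itertuples():
        sl = (slice(int(row.bbox_min_row), int(row.bbox_max_row)),
              slice(int(row.bbox_min_col), int(row.bbox_max_col)))
        yield int(row.label), fov.target[sl], mask.label_map[sl] == row.label, sl


class TestDetectFoci:
    def test_noise_free_recovery_matches_truth_pixel_sets(self):
        cfg = SimulationConfig(model="degradation", survival_fraction=0.2,
                               foci_per_nucleus=(8, 8), noise=False, seed=21)
        fov, truth = simulate_field(cfg)
        mask = segment_nuclei(fov.dapi)
        matches = match_to_truth(mask, truth.nucleus_label_map).set_index("seg_label")
        for label, crop, crop_mask, sl in _per_nucleus_crops(fov, mask):
            foci = detect_foci(crop, crop_mask, parent_nucleus=label)
            assert len(foci) == 8
            detected = np.zeros_like(crop_mask)
            for f in foci:
                detected[f.rows, f.cols] = True
            true_foci = (truth.focus_label_map[sl] > 0) & crop_mask
            np.testing.assert_array_equal(detected, true_foci)

    def test_unirradiated_noise_free_has_no_foci(self, noise_free_config):
        fov, _ = simulate_field(noise_free_config)
        mask = segment_nuclei(fov.dapi)
        for label, crop, crop_mask, _ in _per_nucleus_crops(fov, mask):
            assert detect_foci(crop, crop_mask, parent_nucleus=label) == []

    def test_detection_f1_under_default_noise(self):
        """Centroid-matched F1 >= 0.9 for 10 foci/nucleus at default noise."""
        cfg = SimulationConfig(model="degradation", survival_fraction=0.2,
                               foci_per_nucleus=(10, 10), seed=22)
        fov, truth = simulate_field(cfg)
        mask = segment_nuclei(fov.dapi)
        tp = fp = 0
        n_true = int(truth.per_nucleus_truth["focus_count"].sum())
        true_centroids = []
        for fid in truth.focus_parent:
            rr, cc = np.nonzero(truth.focus_label_map == fid)
            true_centroids.append((rr.mean(), cc.mean()))
        true_centroids = np.array(true_centroids)
        used = np.zeros(len(true_centroids), dtype=bool)
        for label, crop, crop_mask, sl in _per_nucleus_crops(fov, mask):
            for f in detect_foci(crop, crop_mask, parent_nucleus=label):
                cen = np.array([f.centroid[0] + sl[0].start, f.centroid[1] + sl[1].start])
                d = np.linalg.norm(true_centroids - cen, axis=1)
                d[used] = np.inf
                if d.min() <= 2.5:  # within a focus radius
                    used[d.argmin()] = True
                    tp += 1
                else:
                    fp += 1
        precision = tp / max(tp + fp, 1)
        recall = tp / n_true
        f1 = 2 * precision * recall / (precision + recall)
        assert f1 >= 0.9

    def test_offset_invariance_noise_free(self):
        cfg = SimulationConfig(model="degradation", survival_fraction=0.3,
                               noise=False, seed=23)
        fov, _ = simulate_field(cfg)
        mask = segment_nuclei(fov.dapi)
        for label, crop, crop_mask, _ in _per_nucleus_crops(fov, mask):
            base = detect_foci(crop, crop_mask, parent_nucleus=label)
            shifted = detect_foci(crop.astype(int) + 200, crop_mask, parent_nucleus=label)
            assert len(base) == len(shifted)
            for f, g in zip(base, shifted):
                np.testing.assert_array_equal(f.rows, g.rows)
                np.testing.assert_array_equal(f.cols, g.cols)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            detect_foci(np.zeros((8, 8)), np.zeros((8, 8), dtype=bool))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FociParams(k=0).validate()
        with pytest.raises(ValueError):
            FociParams(min_focus_area=0).validate()


class TestNucleusIntensityRecord:
    def test_arithmetic_example(self):
        target = np.array([[10, 10], [20, 20]], dtype=float)
        mask = np.ones((2, 2), dtype=bool)
        # the bottom row is a 2-px focus
        from irifcyto.foci import FocusRegion
        focus = [FocusRegion(1, 1, np.array([1, 1]), np.array([0, 1]), 2, (1.0, 0.5), 20.0)]
        rec = nucleus_intensity_record(target, mask, focus)
        assert rec.mean_all == 15.0
        assert rec.mean_foci == 20.0
        assert rec.mean_nucleoplasm == 10.0

    def test_no_foci_case(self):
        target = np.full((3, 3), 42.0)
        rec = nucleus_intensity_record(target, np.ones((3, 3), bool), [])
        assert rec.mean_foci is None
        assert rec.mean_nucleoplasm == rec.mean_all == 42.0

    def test_empty_nucleus_rejected(self):
        with pytest.raises(ValueError):
            nucleus_intensity_record(np.zeros((3, 3)), np.zeros((3, 3), bool), [])

    def test_weighted_decomposition_exact(self):
        """mean_all equals the area-weighted mix of foci and nucleoplasm means
        for every analyzed nucleus."""
        cfg = SimulationConfig(model="degradation", survival_fraction=0.2, seed=31)
        fov, _ = simulate_field(cfg)
        records = analyze_nuclei(fov.target, segment_nuclei(fov.dapi))
        for r in records:
            if r.mean_foci is None:
                continue
            area_np = r.area - r.focus_area
            recombined = (r.focus_area * r.mean_foci + area_np * r.mean_nucleoplasm) / r.area
            assert abs(recombined - r.mean_all) < 1e-9 * max(abs(r.mean_all), 1)


class TestNormalizedFociIntensity:
    def test_unit_reference(self):
        from irifcyto.foci import NucleusIntensityRecord
        rec = NucleusIntensityRecord(1, 100, 500.0, 500.0, 500.0, 6, 10)
        df = normalized_foci_intensity([rec], reference=500.0)
        assert df["normalized_foci_intensity"].iloc[0] == 1.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            normalized_foci_intensity([], reference=0.0)

    def test_degradation_with_protection_sits_at_one(self):
        """Protected foci stay at the pre-irradiation level, so normalized
        foci intensity is ~1: the no-difference structure between diffuse
        signal before irradiation and focus signal after."""
        base = SimulationConfig(model="unirradiated", n_nuclei=15, seed=41)
        fov0, _ = simulate_field(base)
        ref = reference_diffuse_mean(analyze_nuclei(fov0.target, segment_nuclei(fov0.dapi)))
        fov1, _ = simulate_field(base.with_(model="degradation", survival_fraction=0.2, seed=42))
        recs = analyze_nuclei(fov1.target, segment_nuclei(fov1.dapi))
        mean, sem = summarize_normalized(normalized_foci_intensity(recs, ref))
        assert abs(mean - 1.0) < 0.02

    def test_recruitment_exceeds_one_by_concentration_factor(self):
        """Noise-free recruitment: per-nucleus normalized intensity matches the
        closed-form expectation from r and the area fractions."""
        cfg = SimulationConfig(model="recruitment", recruited_fraction=0.3,
                               noise=False, seed=43)
        fov, truth = simulate_field(cfg)
        mask = segment_nuclei(fov.dapi)
        base = SimulationConfig(model="unirradiated", noise=False, seed=43)
        fov0, _ = simulate_field(base)
        ref = reference_diffuse_mean(analyze_nuclei(fov0.target, segment_nuclei(fov0.dapi)))
        recs = {r.nucleus_id: r for r in analyze_nuclei(fov.target, mask)}
        matches = match_to_truth(mask, truth.nucleus_label_map)
        tt = truth.per_nucleus_truth.set_index("nucleus_id")
        for row in matches.itertuples():
            rec = recs[int(row.seg_label)]
            # expected focus value, clipped at the 12-bit camera ceiling
            expected = min(tt.loc[row.truth_id, "focus_mean"] + 50.0, 4095.0) / ref
            assert expected > 1.5
            assert abs(rec.mean_foci / ref - expected) < 0.01 * expected
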