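import logging

import numpy as np
import pytest

from xlct.geometry import ValidationError
from xlct.metrics import (
    cnr,
    count_components,
    dice,
    evaluate_volume,
    intensity_profile,
    normalize_volume,
)


class TestNormalizeVolume:
    def test_scales_maximum_to_one(self):
        v = np.array([[1.0, 4.0], [2.0, 0.0]])
        out = normalize_volume(v)
        assert out.max() == 1.0
        assert np.allclose(out, v / 4.0)

    def test_all_zero_returned_unchanged_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            out = normalize_volume(np.zeros((2, 2)))
        assert not out.any()
        assert any("unchanged" in r.message for r in caplog.records)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 7, (3, 4, 5))
        once = normalize_volume(v)
        assert np.allclose(normalize_volume(once), once)


class TestDice:
    def test_perfect_overlap(self):
        v = np.zeros((2, 5, 5))
        v[0, 1:4, 1:4] = 1.0
        assert dice(v, v > 0) == 1.0

    def test_disjoint_regions(self):
        v = np.zeros((1, 4, 4))
        v[0, 0, 0] = 1.0
        truth = np.zeros((1, 4, 4), dtype=bool)
        truth[0, 3, 3] = True
        assert dice(v, truth) == 0.0

    def test_worked_example_120_100_80(self):
        recon = np.zeros(400)
        recon[:120] = 1.0
        truth = np.zeros(400, dtype=bool)
        truth[40:140] = True  # overlap = voxels 40..119 -> 80
        d = dice(recon.reshape(4, 10, 10), truth.reshape(4, 10, 10))
        assert d == pytest.approx(160 / 220)
        assert d == pytest.approx(0.7273, abs=5e-5)

    def test_invariant_to_intensity_rescaling(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0, 1, (3, 8, 8))
        truth = rng.uniform(0, 1, (3, 8, 8)) > 0.7
        assert dice(v, truth) == dice(17.3 * v, truth)

    def test_symmetric_in_the_two_masks(self):
        a = np.zeros((2, 6, 6))
        a[0, :3, :3] = 1.0
        b = np.zeros((2, 6, 6))
        b[0, 1:5, 1:5] = 1.0
        assert dice(a, b > 0) == pytest.approx(dice(b, a > 0))

    def test_both_empty_defined_as_one(self):
        assert dice(np.zeros((1, 2, 2)), np.zeros((1, 2, 2), dtype=bool)) == 1.0

    def test_invalid_threshold_and_shape(self):
        v = np.zeros((1, 2, 2))
        with pytest.raises(ValidationError):
            dice(v, v > 0, threshold_frac=1.5)
        with pytest.raises(ValidationError):
            dice(v, np.zeros((2, 2, 2), dtype=bool))


class TestCnr:
    def _two_level(self, contrast=1.0, spread=0.1, shift=0.0, scale=1.0):
        vol = np.zeros(4000)
        roi = np.zeros(4000, dtype=bool)
        roi[:2000] = True
        pm = np.array([1.0, -1.0] * 1000)
        vol[roi] = contrast + spread * pm
        vol[~roi] = spread * pm
        return scale * (vol + shift), roi

    def test_equal_means_give_zero(self):
        vol = np.concatenate([np.array([1.0, -1.0] * 10)] * 2)
        roi = np.zeros(40, dtype=bool)
        roi[:20] = True
        assert cnr(vol, roi, ~roi) == 0.0

    def test_worked_example_value_ten(self):
        vol, roi = self._two_level()  # means 1 and 0, variances both 0.01
        assert cnr(vol, roi, ~roi) == pytest.approx(10.0)

    def test_scale_and_shift_invariance(self):
        vol, roi = self._two_level()
        base = cnr(vol, roi, ~roi)
        assert cnr(3.0 * vol, roi, ~roi) == pytest.approx(base)
        assert cnr(vol + 5.0, roi, ~roi) == pytest.approx(base)

    def test_volume_proportional_weights(self):
        # unequal region sizes: weights are |ROI|/total and |BCK|/total
        vol = np.zeros(300)
        roi = np.zeros(300, dtype=bool)
        roi[:100] = True
        pm100 = np.array([1.0, -1.0] * 50)
        pm200 = np.array([1.0, -1.0] * 100)
        vol[roi] = 1.0 + 0.3 * pm100
        vol[~roi] = 0.1 * pm200
        w_roi = 100 / 300
        expected = 1.0 / np.sqrt(w_roi * 0.09 + (1 - w_roi) * 0.01)
        assert cnr(vol, roi, ~roi) == pytest.approx(expected)

    def test_overlapping_or_empty_masks_raise(self):
        vol = np.zeros(10)
        m = np.ones(10, dtype=bool)
        with pytest.raises(ValidationError):
            cnr(vol, m, m)
        with pytest.raises(ValidationError):
            cnr(vol, m, np.zeros(10, dtype=bool))


class TestIntensityProfile:
    def test_constant_volume_gives_constant_profile(self):
        v = np.full((3, 5, 5), 2.0)
        p = intensity_profile(v, (1, 2, 0), (1, 2, 4), n_samples=9)
        assert np.allclose(p.samples, 1.0)  # normalized

    def test_two_separated_peaks_give_two_maxima(self):
        v = np.zeros((3, 7, 21))
        v[1, 3, 5] = v[1, 3, 15] = 1.0
        from scipy.ndimage import gaussian_filter
        v = gaussian_filter(v, 1.0)
        p = intensity_profile(v, (1, 3, 0), (1, 3, 20), n_samples=21).samples
        interior = p[1:-1]
        n_max = np.sum((interior > p[:-2]) & (interior > p[2:]))
        assert n_max == 2

    def test_two_samples_return_endpoints(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0.1, 1.0, (3, 4, 4))
        nv = normalize_volume(v)
        p = intensity_profile(v, (0, 0, 0), (2, 3, 3), n_samples=2)
        assert p.samples[0] == pytest.approx(nv[0, 0, 0])
        assert p.samples[1] == pytest.approx(nv[2, 3, 3])

    def test_out_of_bounds_endpoint_raises(self):
        with pytest.raises(ValidationError):
            intensity_profile(np.ones((2, 2, 2)), (0, 0, 0), (0, 0, 5))


class TestEvaluateVolume:
    def test_report_fields_and_component_count(self):
        truth = np.zeros((3, 10, 10))
        truth[1, 2:4, 2:4] = 50.0
        recon = truth / 50.0
        rep = evaluate_volume(recon, truth, method="test", case_id="c0")
        assert rep.dice == 1.0
        assert rep.cnr > 0
        assert count_components(recon) == 1


class TestExperimentValidation:
    def test_empty_method_list_rejected(self):
        from xlct.experiments import run_experiment
        with pytest.raises(ValidationError):
            run_experiment({"experiment": "resolution", "methods": []},
                           study=object())

    def test_unknown_experiment_rejected(self):
        from xlct.experiments import run_experiment
        with pytest.raises(ValidationError):
            run_experiment({"experiment": "nope", "methods": ["tfista"]},
                           study=object())

    def test_unknown_method_rejected(self):
        from xlct.experiments import run_experiment
        with pytest.raises(ValidationError):
            run_experiment({"experiment": "noise", "methods": ["magic"]},
                           study=object())

    def test_aggregate_reports_means(self):
        from xlct.experiments import aggregate_reports
        from xlct.metrics import MetricReport
        reports = [MetricReport("m", "a", 0.2, 1.0),
                   MetricReport("m", "b", 0.4, 3.0)]
        agg = aggregate_reports(reports)
        assert agg["m"]["mean_dice"] == pytest.approx(0.3)
        assert agg["m"]["mean_cnr"] == pytest.approx(2.0)
        assert agg["m"]["n_cases"] == 2
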