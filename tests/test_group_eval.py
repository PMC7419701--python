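"""Group averaging, rank AUC vs exhaustive oracle, vertical-average bootstrap."""

import numpy as np
import pytest
from scipy import stats

import langmap
from langmap.errors import (ComparisonError, DegeneracyError, ParameterError,
                            ShapeError)
from langmap.group_eval import (RocResult, compare_methods, group_average,
                                roc_auc, roc_curve_vertical, summarize_cohort)


def pairwise_auc_oracle(scores, labels):
    """O(n^2) concordant-pair fraction, ties counted 1/2."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestGroupAverage:
    def test_single_map_identity(self):
        m = np.random.default_rng(0).random((5, 5, 5))
        assert np.array_equal(group_average([m]).volume, m)

    def test_two_maps_halved_sum(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((2, 4, 4, 4))
        assert np.allclose(group_average([a, b]).volume, (a + b) / 2, atol=0)

    def test_many_maps_match_summation_oracle(self):
        rng = np.random.default_rng(2)
        maps = [rng.random((6, 6, 6)) for _ in range(35)]
        total = np.zeros((6, 6, 6))
        for m in maps:
            total += m
        assert np.allclose(group_average(maps).volume, total / 35, atol=1e-12)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            group_average([np.zeros((4, 4, 4)), np.zeros((5, 5, 5))])


class TestAuc:
    def test_perfect_separation(self):
        s = np.array([0.9, 0.8, 0.4, 0.2])
        t = np.array([True, True, False, False])
        assert roc_auc(s, t) == 1.0

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(10, 501))
            scores = np.round(rng.standard_normal(n), 2)  # force ties
            labels = rng.random(n) < rng.uniform(0.2, 0.8)
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                pairwise_auc_oracle(scores, labels), abs=1e-10)

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(4)
        aucs = []
        for _ in range(100):
            s = rng.standard_normal(1000)
            t = rng.random(1000) < 0.5
            aucs.append(roc_auc(s, t))
        assert 0.45 < np.mean(aucs) < 0.55
        assert min(aucs) > 0.4 and max(aucs) < 0.6

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        s = rng.standard_normal(300)
        t = rng.random(300) < 0.4
        base = roc_auc(s, t)
        assert roc_auc(np.exp(s), t) == pytest.approx(base, abs=1e-12)
        assert roc_auc(3.0 * s + 7.0, t) == pytest.approx(base, abs=1e-12)

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(6)
        s = rng.standard_normal(257)  # continuous: tie-free
        t = rng.random(257) < 0.5
        assert roc_auc(-s, t) == pytest.approx(1.0 - roc_auc(s, t), abs=1e-12)

    def test_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(7)
        s = np.round(rng.standard_normal(400), 1)
        t = rng.random(400) < 0.3
        assert roc_auc(s, t) == pytest.approx(roc_auc_score(t, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DegeneracyError):
            roc_auc(np.arange(5.0), np.ones(5, bool))


class TestVerticalAveragedRoc:
    def test_perfect_scores(self):
        s = np.r_[np.ones(50), np.zeros(50)]
        t = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        res = roc_curve_vertical(s, t, n_boot=200, seed=0)
        assert res.auc == 1.0
        assert res.auc_ci == (1.0, 1.0)
        assert np.all(res.tpr_mean[res.fpr_grid > 0] == 1.0)

    def test_alpha_one_degenerate_band(self):
        rng = np.random.default_rng(0)
        s = rng.standard_normal(200)
        t = rng.random(200) < 0.5
        res = roc_curve_vertical(s, t, n_boot=100, alpha=1.0, seed=0)
        assert np.allclose(res.tpr_ci[0], res.tpr_ci[1])

    def test_small_n_boot_rejected(self):
        with pytest.raises(ParameterError):
            roc_curve_vertical(np.arange(10.0), np.arange(10) < 5, n_boot=5)

    def test_tpr_band_monotone_and_contains_mean(self):
        rng = np.random.default_rng(1)
        s = rng.standard_normal(300) + (rng.random(300) < 0.5) * 1.0
        t = s > 0.5
        s = s + rng.standard_normal(300)
        res = roc_curve_vertical(s, t, n_boot=500, seed=2)
        assert np.all(np.diff(res.tpr_mean) >= -1e-12)
        assert np.all(res.tpr_ci[0] <= res.tpr_ci[1] + 1e-12)
        assert res.auc_ci[0] <= res.auc <= res.auc_ci[1]

    def test_binormal_ci_covers_closed_form(self):
        """Binormal scenario: AUC = Phi(d / sqrt(2)); the bootstrap CI should
        cover it (seeded single instance; the calibration rate is asserted in
        the acceptance suite)."""
        rng = np.random.default_rng(3)
        d = 1.0
        truth_auc = stats.norm.cdf(d / np.sqrt(2))
        n = 300
        s = np.r_[rng.standard_normal(n) + d, rng.standard_normal(n)]
        t = np.r_[np.ones(n, bool), np.zeros(n, bool)]
        res = roc_curve_vertical(s, t, n_boot=500, seed=4)
        assert res.auc_ci[0] <= truth_auc <= res.auc_ci[1]

    def test_vertical_average_converges_to_sample_roc(self):
        rng = np.random.default_rng(5)
        n = 2000
        s = np.r_[rng.standard_normal(n) + 1.5, rng.standard_normal(n)]
        t = np.r_[np.ones(n, bool), np.zeros(n, bool)]
        res = roc_curve_vertical(s, t, n_boot=2000, seed=6)
        from langmap.group_eval import _roc_points
        fpr, tpr = _roc_points(s, t)
        sample = np.interp(res.fpr_grid, fpr, tpr)
        assert np.abs(res.tpr_mean - sample).max() < 0.02

    def test_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(7)
        s = rng.standard_normal(100)
        t = rng.random(100) < 0.5
        res = roc_curve_vertical(s, t, n_boot=50, seed=0, truth_tag="broca")
        p = tmp_path / "roc.json"
        res.to_json(str(p))
        import json
        back = RocResult.from_dict(json.load(open(p)))
        assert back.auc == res.auc
        assert np.allclose(back.tpr_mean, res.tpr_mean)


class TestCompareMethods:
    def _res(self, auc, ci, tag="broca"):
        g = np.linspace(0, 1, 11)
        return RocResult(g, g, (g, g), auc, ci, 100, 0.05, truth_tag=tag)

    def test_identical_inputs(self):
        a = self._res(0.9, (0.85, 0.95))
        comp = compare_methods(a, a)
        assert comp.auc_difference == 0.0 and comp.ci_overlap

    def test_disjoint_intervals(self):
        comp = compare_methods(self._res(0.65, (0.6, 0.7)),
                               self._res(0.85, (0.8, 0.9)))
        assert not comp.ci_overlap

    def test_mismatched_truth_rejected(self):
        with pytest.raises(ComparisonError):
            compare_methods(self._res(0.9, (0.8, 1.0), "broca"),
                            self._res(0.9, (0.8, 1.0), "wernicke"))

    def test_same_scores_two_seeds_overlap(self):
        rng = np.random.default_rng(8)
        s = np.r_[rng.standard_normal(200) + 1, rng.standard_normal(200)]
        t = np.r_[np.ones(200, bool), np.zeros(200, bool)]
        overlaps = []
        for rep in range(20):
            a = roc_curve_vertical(s, t, n_boot=200, seed=2 * rep,
                                   truth_tag="x")
            b = roc_curve_vertical(s, t, n_boot=200, seed=2 * rep + 1,
                                   truth_tag="x")
            overlaps.append(compare_methods(a, b).ci_overlap)
        assert np.mean(overlaps) >= 0.99


@pytest.fixture(scope="module")
def table():
    return langmap.load_cohort_table(langmap.packaged_cohort_path())


class TestCohortSummary:

    def test_mean_volume_matches_printed_value(self, table):
        s = summarize_cohort(table)
        assert round(s["mean_volume_ml"], 1) == 43.8

    def test_rs005_total_is_range_floor(self, table):
        s = summarize_cohort(table)
        assert s["total_volume_ml"]["RS_005"] == pytest.approx(1.4)

    def test_single_patient_mean(self):
        from langmap.phantom import CohortTable, PatientRecord
        t = CohortTable((PatientRecord("P1", "20-25", "R", 0.1,
                                       (("Left frontal", 7.5),), "Glioma"),))
        s = summarize_cohort(t)
        assert s["mean_volume_ml"] == 7.5
        assert s["hemisphere_counts"] == {"left": 1}

    def test_pathology_and_hemisphere_counts(self, table):
        s = summarize_cohort(table)
        assert sum(s["pathology_counts"].values()) == 35
        assert s["hemisphere_counts"]["left"] == 28
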