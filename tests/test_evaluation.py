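import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import (f1_score, precision_recall_fscore_support,
                             roc_auc_score)

from ulcerstage.evaluation import (auc_interpretation, brier_score,
                                   calibration_grade, calibration_report,
                                   default_severity_weights,
                                   expected_calibration_error, hanley_mcneil_se,
                                   mann_whitney_auc, paired_fold_test,
                                   roc_auc_ovr, roc_curve_points,
                                   severity_weighted_error, summary_metrics,
                                   trapezoidal_auc, SeverityWeightMatrix)
from ulcerstage.taxonomy import DEFAULT_TAXONOMY


class TestSummaryMetrics:
    def test_perfect_predictions(self):
        y = ["he", "s1", "s2", "s3", "s4", "un"]
        rep = summary_metrics(y, y)
        assert rep.accuracy == 1.0
        assert rep.macro_f1 == 1.0
        assert np.array_equal(rep.confusion_normalized, np.eye(6))

    def test_binary_all_wrong_zero_convention(self):
        rep = summary_metrics(["he", "s1"], ["s1", "he"])
        for lab in ("he", "s1"):
            assert rep.per_class[lab] == {"precision": 0.0, "recall": 0.0,
                                          "f1": 0.0, "support": 1}

    def test_three_class_toy_hand_confusion_table(self):
        """true AABBCC vs pred ABBBCC: per-class F1 = (2/3, 0.8, 1.0)."""
        true = ["he", "he", "s1", "s1", "s2", "s2"]
        pred = ["he", "s1", "s1", "s1", "s2", "s2"]
        rep = summary_metrics(true, pred)
        assert rep.per_class["he"]["f1"] == pytest.approx(2 / 3)
        assert rep.per_class["s1"]["f1"] == pytest.approx(0.8)
        assert rep.per_class["s2"]["f1"] == pytest.approx(1.0)

    def test_agrees_with_reference_implementation_on_random_instances(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            t = rng.integers(0, 6, 40)
            p = rng.integers(0, 6, 40)
            rep = summary_metrics(t, p)
            pr, rc, f1, _ = precision_recall_fscore_support(
                t, p, labels=range(6), zero_division=0)
            assert rep.macro["f1"] == pytest.approx(f1.mean(), abs=1e-12)
            assert rep.macro["precision"] == pytest.approx(pr.mean(), abs=1e-12)
            assert rep.weighted["f1"] == pytest.approx(
                f1_score(t, p, labels=range(6), average="weighted",
                         zero_division=0), abs=1e-12)

    def test_weighted_equals_macro_with_equal_supports(self):
        rng = np.random.default_rng(1)
        t = np.repeat(np.arange(6), 10)
        p = rng.integers(0, 6, 60)
        rep = summary_metrics(t, p)
        assert rep.weighted["f1"] == pytest.approx(rep.macro["f1"], abs=1e-12)

    def test_confusion_rows_normalize_for_supported_classes(self):
        rng = np.random.default_rng(2)
        t = rng.integers(0, 6, 50)
        rep = summary_metrics(t, rng.integers(0, 6, 50))
        sums = rep.confusion_normalized.sum(axis=1)
        for c in range(6):
            if rep.per_class[DEFAULT_TAXONOMY.labels[c]]["support"]:
                assert sums[c] == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summary_metrics([], [])


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        pos = np.array([True, True, False, False])
        fpr, tpr = roc_curve_points(scores, pos)
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)
        auc = trapezoidal_auc(fpr, tpr)
        assert auc == 1.0
        assert hanley_mcneil_se(auc, 2, 2) == 0.0
        assert auc_interpretation(auc).startswith("Excellent")

    def test_all_pairs_concordance_toy(self):
        """pos {0.9, 0.6}, neg {0.7, 0.4}: 3 of 4 pairs concordant -> 0.75."""
        pos, neg = [0.9, 0.6], [0.7, 0.4]
        scores = np.array(pos + neg)
        mask = np.array([1, 1, 0, 0], bool)
        auc = trapezoidal_auc(*roc_curve_points(scores, mask))
        assert auc == pytest.approx(0.75, abs=1e-12)
        assert mann_whitney_auc(pos, neg) == pytest.approx(0.75, abs=1e-12)

    def test_trapezoid_equals_concordance_on_random_instances(self):
        rng = np.random.default_rng(3)
        for trial in range(100):
            n = int(rng.integers(8, 40))
            scores = np.round(rng.random(n), 2)  # duplicates force tie handling
            pos = rng.random(n) < 0.4
            if pos.all() or not pos.any():
                continue
            auc = trapezoidal_auc(*roc_curve_points(scores, pos))
            mw = mann_whitney_auc(scores[pos], scores[~pos])
            assert auc == pytest.approx(mw, abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(pos, scores), abs=1e-12)

    def test_band_edges(self):
        assert auc_interpretation(0.92) == "Excellent (0.90-1.00)"
        assert auc_interpretation(0.90) == "Excellent (0.90-1.00)"
        assert auc_interpretation(0.85) == "Good (0.80-0.90)"
        assert auc_interpretation(0.55) == "No better than random (0.50-0.60)"

    def test_hanley_mcneil_closed_form(self):
        a, n1, n2 = 0.8, 10, 20
        q1 = a / (2 - a)
        q2 = 2 * a * a / (1 + a)
        expected = np.sqrt((a * (1 - a) + 9 * (q1 - a * a) + 19 * (q2 - a * a))
                           / (n1 * n2))
        assert hanley_mcneil_se(a, n1, n2) == pytest.approx(expected, abs=1e-15)

    def test_ovr_macro_is_mean_of_per_class(self, random_simplex_rows):
        probs = random_simplex_rows(60, seed=4)
        y = np.random.default_rng(5).integers(0, 6, 60)
        res = roc_auc_ovr(probs, y)
        per = [r["auc"] for r in res.per_class.values() if r["auc"] is not None]
        assert res.macro_auc == pytest.approx(np.mean(per), abs=1e-12)
        for r in res.per_class.values():
            if r["auc"] is not None:
                assert 0.0 <= r["ci95"][0] <= r["ci95"][1] <= 1.0

    def test_degenerate_class_reported_undefined(self, random_simplex_rows):
        probs = random_simplex_rows(10, seed=6)
        y = np.zeros(10, dtype=int)  # only 'he' present
        res = roc_auc_ovr(probs, y)
        assert res.per_class["he"]["auc"] is None
        assert res.per_class["s4"]["auc"] is None

    def test_micro_auc_pools_per_decision(self, random_simplex_rows):
        probs = random_simplex_rows(25, seed=7)
        y = np.random.default_rng(8).integers(0, 6, 25)
        res = roc_auc_ovr(probs, y)
        onehot = np.eye(6, dtype=bool)[y]
        assert res.micro_auc == pytest.approx(
            roc_auc_score(onehot.ravel(), probs.ravel()), abs=1e-12)


class TestCalibration:
    def test_perfectly_confident_and_correct(self):
        ece, _ = expected_calibration_error(np.ones(10), np.ones(10))
        assert ece == 0.0

    def test_single_bin_hand_computation(self):
        """Two predictions at 0.9, both wrong: ECE = |0 - 0.9| = 0.9."""
        ece, table = expected_calibration_error([0.9, 0.9], [0, 0])
        assert ece == pytest.approx(0.9, abs=1e-12)
        assert table[8]["count"] == 2

    def test_bin_accuracy_equals_bin_confidence(self):
        """Four at 0.75 with three correct: |0.75 - 0.75| = 0."""
        ece, _ = expected_calibration_error([0.75] * 4, [1, 1, 1, 0])
        assert ece == pytest.approx(0.0, abs=1e-12)

    def test_bins_are_right_closed(self):
        # 0.1 falls in bin 0 (0, 0.1]; 0.100001 falls in bin 1
        _, table = expected_calibration_error([0.1, 0.100001], [1, 0])
        assert table[0]["count"] == 1 and table[1]["count"] == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            expected_calibration_error([], [])

    def test_brier_examples(self):
        assert brier_score([1.0, 0.0], [1, 0]) == 0.0
        assert brier_score([0.5], [1]) == pytest.approx(0.25)
        assert brier_score([0.5] * 10, [1, 0] * 5) == pytest.approx(0.25)

    @pytest.mark.parametrize("ece,grade", [
        (0.0227, "Excellent"),
        (0.0622, "Good"),
        (0.05, "Good"),  # lower boundary belongs to the upper band
        (0.10, "Fair"),
        (0.1499, "Fair"),
        (0.15, "Poor"),
    ])
    def test_grade_bands(self, ece, grade):
        assert calibration_grade(ece) == grade

    def test_report_per_class_and_overall(self, random_simplex_rows):
        probs = random_simplex_rows(40, seed=9)
        y = np.random.default_rng(10).integers(0, 6, 40)
        rep = calibration_report(probs, y)
        assert set(rep.per_class) == set(DEFAULT_TAXONOMY.labels)
        for r in rep.per_class.values():
            assert 0.0 <= r["ece"] <= 1.0
            assert 0.0 <= r["brier"] <= 1.0
            assert sum(b["count"] for b in r["bins"]) == 40
        assert rep.overall_grade == calibration_grade(rep.overall_ece)

    def test_calibrated_stream_converges_to_zero_ece(self):
        rng = np.random.default_rng(11)
        conf = rng.random(100_000)
        outcome = (rng.random(100_000) < conf).astype(float)
        ece, _ = expected_calibration_error(conf, outcome)
        assert ece < 0.02


class TestSeverityWeighting:
    def test_perfect_confusion_costs_zero(self):
        conf = np.diag([5, 5, 5, 5, 5, 5])
        assert severity_weighted_error(conf, default_severity_weights()) == 0.0

    def test_unit_weights_reduce_to_error_rate(self):
        rng = np.random.default_rng(12)
        conf = rng.integers(0, 10, (6, 6))
        w = np.ones((6, 6)) - np.eye(6)
        err = severity_weighted_error(conf, SeverityWeightMatrix(tuple(map(tuple, w))))
        assert err == pytest.approx(1.0 - np.trace(conf) / conf.sum())

    def test_extreme_stage_confusion_costs_squared_distance(self):
        """One s1 -> s4 confusion under (i-j)^2 weights costs 9/N."""
        conf = np.diag([2, 2, 2, 2, 2, 2]).astype(float)
        conf[1, 4] += 1  # true s1 predicted s4
        err = severity_weighted_error(conf, default_severity_weights())
        assert err == pytest.approx(9.0 / conf.sum())

    def test_negative_weights_rejected(self):
        w = -np.ones((6, 6)) + np.eye(6)
        with pytest.raises(ValueError):
            SeverityWeightMatrix(tuple(map(tuple, w)))


class TestPairedFoldTest:
    def test_hand_t_statistic(self):
        """d = (.01,.02,.03,.01,.03): t = 0.02/(0.01/sqrt(5)) = 4.4721, df 4."""
        a = np.array([0.91, 0.92, 0.93, 0.91, 0.93])
        b = np.array([0.90, 0.90, 0.90, 0.90, 0.90])
        res = paired_fold_test(a, b)
        assert res.df == 4
        assert res.t_statistic == pytest.approx(2 * np.sqrt(5), abs=1e-10)

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(13)
        a = rng.random(5)
        b = rng.random(5)
        res = paired_fold_test(a, b)
        ref = stats.ttest_rel(a, b)
        assert res.t_statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)
        lo, hi = ref.confidence_interval(0.95)
        assert res.ci95 == (pytest.approx(lo, abs=1e-10), pytest.approx(hi, abs=1e-10))

    def test_identical_methods_report_no_difference(self):
        a = np.array([0.9, 0.8, 0.7, 0.9, 0.85])
        res = paired_fold_test(a, a.copy())
        assert res.t_statistic == 0.0
        assert res.p_value == 1.0

    def test_five_folds_have_df_four(self):
        res = paired_fold_test(np.arange(5.0), np.arange(5.0) * 1.1)
        assert res.df == 4

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            paired_fold_test([0.9], [0.8])
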