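"""Evaluation battery: confusion counts, metrics, ROC/AUC, normality."""

import numpy as np
import pytest
from scipy import stats

from skelpose import (class_metrics, confusion_matrix, dataset_summary,
                      evaluate_predictions, mean_class_accuracy, mean_roc,
                      normality_test, roc_curve, summarize, total_accuracy)


def counting_oracle(y_true, y_pred, cls):
    """Brute-force per-frame TP/TN/FP/FN counts for one class."""
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if p == cls and t == cls:
            tp += 1
        elif p == cls and t != cls:
            fp += 1
        elif p != cls and t == cls:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn


class TestConfusionMatrix:
    def test_perfect_diagonal(self):
        cm = confusion_matrix([1, 2, 3, 4], [1, 2, 3, 4])
        assert np.array_equal(cm, np.eye(4, dtype=int))

    def test_hand_counted_cells(self):
        cm = confusion_matrix([1, 1, 2], [1, 2, 2])
        expected = np.zeros((4, 4), dtype=int)
        expected[0, 0] = 1   # predicted 1, actual 1
        expected[1, 0] = 1   # predicted 2, actual 1
        expected[1, 1] = 1   # predicted 2, actual 2
        assert np.array_equal(cm, expected)

    def test_rows_are_predictions_columns_actual(self):
        cm = confusion_matrix([3], [1])
        assert cm[0, 2] == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no frames"):
            confusion_matrix([], [])

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion_matrix([1, 5], [1, 1])


class TestClassMetrics:
    def test_perfect_predictions_all_ones(self):
        cm = confusion_matrix([1, 2, 3, 4] * 3, [1, 2, 3, 4] * 3)
        for c in (1, 2, 3, 4):
            m = class_metrics(cm, c)
            assert (m.accuracy, m.sensitivity, m.specificity, m.precision,
                    m.f_score) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_direct_formula_case(self):
        # TP=3, TN=5, FP=1, FN=1 for class 1
        y_true = [1, 1, 1, 1, 2, 2, 3, 3, 4, 4]
        y_pred = [1, 1, 1, 2, 1, 2, 3, 3, 4, 4]
        m = class_metrics(confusion_matrix(y_true, y_pred), 1)
        assert (m.tp, m.tn, m.fp, m.fn) == (3, 5, 1, 1)
        assert m.accuracy == pytest.approx(0.8)
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(5 / 6)
        assert m.precision == pytest.approx(0.75)
        assert m.f_score == pytest.approx(0.75)

    def test_matches_counting_oracle_on_random_labels(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(4, 60)
            y_true = rng.integers(1, 5, size=n)
            y_pred = rng.integers(1, 5, size=n)
            cm = confusion_matrix(y_true, y_pred)
            for c in (1, 2, 3, 4):
                tp, tn, fp, fn = counting_oracle(y_true, y_pred, c)
                m = class_metrics(cm, c)
                assert (m.tp, m.tn, m.fp, m.fn) == (tp, tn, fp, fn)
                assert m.accuracy == (tp + tn) / n
                assert m.sensitivity == (tp / (tp + fn) if tp + fn else 0.0)
                assert m.specificity == (tn / (tn + fp) if tn + fp else 0.0)
                assert m.precision == (tp / (tp + fp) if tp + fp else 0.0)

    def test_counts_partition_total(self):
        rng = np.random.default_rng(1)
        y_true = rng.integers(1, 5, size=500)
        y_pred = rng.integers(1, 5, size=500)
        cm = confusion_matrix(y_true, y_pred)
        tps = 0
        for c in (1, 2, 3, 4):
            m = class_metrics(cm, c)
            assert m.tp + m.tn + m.fp + m.fn == 500
            tps += m.tp
        assert tps == np.trace(cm)


class TestAccuracies:
    def test_identity_matrix_is_one(self):
        assert total_accuracy(np.eye(4) * 5) == 1.0

    def test_trace_over_total(self):
        cm = np.zeros((4, 4))
        cm[0, 0] = 839
        cm[1, 0] = 161
        assert total_accuracy(cm) == pytest.approx(0.839)

    def test_mean_class_accuracy_differs_from_total(self):
        cm = confusion_matrix([1, 1, 2, 3], [1, 2, 2, 3])
        assert mean_class_accuracy(cm) != total_accuracy(cm)


class TestROC:
    def test_perfect_separation_auc_one(self):
        y = np.array([1, 1, 2, 2])
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        curve = roc_curve(y, scores, 1)
        assert curve.auc == 1.0
        assert any((f == 0 and t == 1) for f, t in zip(curve.fpr, curve.tpr))

    def test_hand_swept_thresholds(self):
        # scores 0.9, 0.8, 0.3 with labels +, -, + -> AUC 0.5
        curve = roc_curve(np.array([1, 2, 1]), np.array([0.9, 0.8, 0.3]), 1)
        assert curve.auc == pytest.approx(0.5)

    def test_endpoints(self):
        rng = np.random.default_rng(0)
        curve = roc_curve(rng.integers(1, 3, 50), rng.random(50), 1)
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(curve.fpr) >= 0)

    def test_auc_equals_mann_whitney_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(10, 80))
            y = rng.integers(1, 3, size=n)
            if len(set(y)) < 2:
                continue
            scores = rng.random(n)
            curve = roc_curve(y, scores, 1)
            pos, neg = scores[y == 1], scores[y != 1]
            u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
            assert curve.auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_label_independent_scores_auc_near_half(self):
        rng = np.random.default_rng(3)
        y = rng.integers(1, 3, size=10_000)
        scores = rng.random(10_000)
        assert 0.47 <= roc_curve(y, scores, 1).auc <= 0.53

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="ROC undefined"):
            roc_curve(np.array([1, 1]), np.array([0.4, 0.6]), 1)

    def test_mean_roc_of_identical_curves_is_the_curve(self):
        rng = np.random.default_rng(4)
        curve = roc_curve(rng.integers(1, 3, 100), rng.random(100), 1)
        mean = mean_roc([curve, curve, curve])
        from skelpose.evaluation import interp_roc
        assert np.allclose(mean.tpr, interp_roc(curve), atol=1e-12)

    def test_mean_roc_is_monotone(self):
        rng = np.random.default_rng(5)
        curves = [roc_curve(rng.integers(1, 3, 60), rng.random(60), 1)
                  for _ in range(5)]
        mean = mean_roc(curves)
        assert np.all(np.diff(mean.tpr) >= -1e-12)
        assert 0.0 <= mean.auc <= 1.0


class TestNormality:
    def test_gaussian_samples_usually_pass(self):
        rng = np.random.default_rng(0)
        passes = sum(normality_test(rng.normal(size=50))[1] > 0.05
                     for _ in range(100))
        assert passes >= 90

    def test_bimodal_sample_fails(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([np.zeros(25), np.ones(25)])
        values += rng.normal(scale=1e-3, size=50)
        assert normality_test(values)[1] < 0.01

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="3..5000"):
            normality_test([0.1, 0.2])

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normality_test([0.5] * 10)


class TestSummaries:
    def test_mean_of_identical_reports_is_the_report(self):
        rng = np.random.default_rng(6)
        y = rng.integers(1, 5, 100)
        p = rng.integers(1, 5, 100)
        probs = rng.dirichlet(np.ones(4), size=100)
        report = evaluate_predictions(y, p, probs)
        s = summarize([report, report])
        assert s["total_accuracy"][0] == pytest.approx(report.total_accuracy)
        assert s["total_accuracy"][1] == 0.0
        assert np.allclose(s["mean_confusion"], report.confusion)

    def test_dataset_arithmetic(self):
        s = dataset_summary({1: 3, 2: 5, 3: 2, 4: 10})
        assert s["total"] == 20
        assert s["proportions"][4] == 0.5
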