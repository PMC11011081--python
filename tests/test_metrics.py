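"""Tests for the evaluation protocol.

Expected values for the per-class rate arithmetic were frozen from hand
evaluation of the one-vs-rest formulas; curve construction is checked
against brute-force threshold enumeration and against scikit-learn as an
independent reference.
"""

import numpy as np
import pytest
from sklearn import metrics as skm

from pbatn.metrics import (
    ClassMetrics,
    class_metrics,
    confusion_matrix,
    f1_score,
    macro_average,
    macro_roc,
    mean_average_precision,
    metric_report,
    micro_accuracy,
    micro_roc,
    pr_curve,
    roc_curve,
    round2,
)


class TestConfusionMatrix:
    def test_perfect_predictions_balanced(self):
        y = np.repeat(np.arange(6), 200)
        cm = confusion_matrix(y, y, 6)
        np.testing.assert_array_equal(np.diag(cm.counts), 200)
        assert cm.total == 1200

    def test_single_column_when_one_class_predicted(self):
        y_true = np.array([0, 1, 2, 3, 4, 5, 1, 2])
        cm = confusion_matrix(y_true, np.zeros_like(y_true), 6)
        assert cm.counts[:, 0].sum() == 8
        assert cm.counts[:, 1:].sum() == 0

    def test_marginals_match_counting_oracle(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 4, 500)
        y_pred = rng.integers(0, 4, 500)
        cm = confusion_matrix(y_true, y_pred, 4)
        for k in range(4):
            assert cm.counts[k].sum() == np.sum(y_true == k)
            assert cm.counts[:, k].sum() == np.sum(y_pred == k)
            tp, tn, fp, fn = cm.one_vs_rest(k)
            assert tp + tn + fp + fn == cm.total

    def test_out_of_range_label_names_index(self):
        with pytest.raises(ValueError, match="index 2"):
            confusion_matrix([0, 1, 7], [0, 1, 1], 6)


class TestClassMetrics:
    def test_f1_from_printed_precision_recall(self):
        # frozen from the harmonic-mean formula at 2-decimal rounding
        assert round2(f1_score(93.00, 100.00)) == 96.37
        assert round2(f1_score(98.50, 97.50)) == 98.00

    def test_hand_counted_small_matrix(self):
        # class 0: Tp=2, Fn=1, Fp=1, Tn=2, total 6
        cm = confusion_matrix([0, 0, 0, 1, 1, 1], [0, 0, 1, 0, 1, 1], 2)
        m = class_metrics(cm, 0)
        assert m.accuracy == pytest.approx(100 * 4 / 6)
        assert m.recall == pytest.approx(100 * 2 / 3)
        assert m.precision == pytest.approx(100 * 2 / 3)
        assert m.fpr == pytest.approx(100 * 1 / 3)
        assert m.specificity == pytest.approx(100 * 2 / 3)
        assert not m.degenerate

    def test_empty_class_flagged_zeros(self):
        cm = confusion_matrix([0, 0, 1, 1], [0, 0, 1, 1], 3)
        m = class_metrics(cm, 2)
        assert m.degenerate
        assert m.recall == 0.0 and m.precision == 0.0 and m.f1 == 0.0

    def test_fpr_specificity_complementary(self):
        """One-vs-rest FPR and specificity sum to 100% for every class."""
        rng = np.random.default_rng(1)
        cm = confusion_matrix(rng.integers(0, 5, 300), rng.integers(0, 5, 300), 5)
        for k in range(5):
            m = class_metrics(cm, k)
            assert m.fpr + m.specificity == pytest.approx(100.0)

    def test_f1_is_harmonic_mean_of_percentage_rates(self):
        """F1 stays on the same percentage scale as precision and recall."""
        rng = np.random.default_rng(10)
        cm = confusion_matrix(rng.integers(0, 4, 200), rng.integers(0, 4, 200), 4)
        for k in range(4):
            m = class_metrics(cm, k)
            assert m.f1 == pytest.approx(f1_score(m.precision, m.recall))
            assert 0.0 <= m.f1 <= 100.0

    def test_micro_accuracy_is_trace_over_total(self):
        rng = np.random.default_rng(2)
        y_true = rng.integers(0, 6, 400)
        y_pred = rng.integers(0, 6, 400)
        cm = confusion_matrix(y_true, y_pred, 6)
        assert micro_accuracy(cm) == pytest.approx(100 * np.mean(y_true == y_pred))


class TestMacroAverage:
    def test_identical_classes_average_to_themselves(self):
        m = ClassMetrics(90.0, 80.0, 70.0, 5.0, 95.0, 74.67)
        avg = macro_average([m, m, m])
        assert avg.as_dict() == m.as_dict()

    def test_map_equals_macro_precision(self):
        rng = np.random.default_rng(3)
        cm = confusion_matrix(rng.integers(0, 6, 600), rng.integers(0, 6, 600), 6)
        per_class = [class_metrics(cm, k) for k in range(6)]
        assert mean_average_precision(cm) == pytest.approx(
            macro_average(per_class).precision
        )


class TestPRCurve:
    def test_perfect_separation_bep_one(self):
        scores = np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
        labels = np.array([1, 1, 1, 0, 0, 0])
        curve = pr_curve(scores, labels)
        assert curve.bep == pytest.approx(1.0)

    def test_bep_f1_equals_common_value(self):
        rng = np.random.default_rng(4)
        scores = rng.random(200)
        labels = (rng.random(200) < 0.4).astype(int)
        curve = pr_curve(scores, labels)
        # at precision = recall = bep, the harmonic mean is that value
        assert f1_score(curve.bep, curve.bep) == pytest.approx(curve.bep)

    def test_matches_bruteforce_threshold_enumeration(self):
        scores = np.array([0.9, 0.7, 0.7, 0.4, 0.3, 0.1])
        labels = np.array([1, 0, 1, 1, 0, 0])
        curve = pr_curve(scores, labels)
        for thr, r, p in zip(curve.thresholds, curve.x, curve.y):
            pred = scores >= thr
            tp = np.sum(pred & (labels == 1))
            assert p == pytest.approx(tp / pred.sum())
            assert r == pytest.approx(tp / labels.sum())

    def test_single_class_degenerate(self):
        assert pr_curve(np.array([0.1, 0.2]), np.array([1, 1])).degenerate


class TestROCCurve:
    def test_perfect_classifier_auc_one(self):
        curve = roc_curve(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert curve.auc == pytest.approx(1.0)
        assert curve.x[0] == 0.0 and curve.y[0] == 0.0
        assert curve.x[-1] == 1.0 and curve.y[-1] == 1.0

    def test_score_negation_flips_auc(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=300)
        labels = (rng.random(300) < 0.5).astype(int)
        a = roc_curve(scores, labels).auc
        b = roc_curve(-scores, labels).auc
        assert a + b == pytest.approx(1.0)

    def test_auc_matches_sklearn(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            scores = rng.normal(size=150)
            labels = (rng.random(150) < 0.3).astype(int)
            if labels.sum() in (0, 150):
                continue
            assert roc_curve(scores, labels).auc == pytest.approx(
                skm.roc_auc_score(labels, scores), abs=1e-10
            )

    def test_micro_roc_matches_sklearn_micro(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 4, 120)
        scores = rng.random((120, 4))
        got = micro_roc(scores, labels).auc
        onehot = np.eye(4, dtype=int)[labels]
        want = skm.roc_auc_score(onehot, scores, average="micro")
        assert got == pytest.approx(want, abs=1e-10)

    def test_macro_roc_between_best_and_worst_class(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 3, 200)
        scores = rng.random((200, 3))
        scores[np.arange(200), labels] += 0.5  # informative
        per_class = [
            roc_curve(scores[:, c], (labels == c).astype(int)).auc for c in range(3)
        ]
        macro = macro_roc(scores, labels).auc
        assert min(per_class) - 0.02 <= macro <= max(per_class) + 0.02


class TestReport:
    def test_report_is_internally_consistent(self):
        rng = np.random.default_rng(9)
        labels = rng.integers(0, 6, 300)
        scores = rng.random((300, 6))
        scores[np.arange(300), labels] += 1.0
        preds = scores.argmax(axis=1)
        report = metric_report(labels, preds, [f"c{i}" for i in range(6)], scores)
        assert report.map_score == pytest.approx(
            mean_average_precision(report.cm)
        )
        assert report.macro.precision == pytest.approx(
            np.mean([m.precision for m in report.per_class])
        )
        d = report.as_dict()
        assert set(d["per_class"]) == {f"c{i}" for i in range(6)}
        assert "macro" in d["auc"] and "micro" in d["auc"]


def test_round2_is_half_up():
    assert round2(97.475) == 97.48
    assert round2(96.365) == 96.37
    assert round2(1.005) == 1.01
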