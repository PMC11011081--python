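"""Multiclass evaluation protocol.

Per-class metrics use a one-vs-rest reduction of the K×K confusion matrix:
for class k, Tp is the diagonal cell, Fn the rest of its row, Fp the rest of
its column, and Tn everything else, with Sumd the grand total.  The six
rates are

    accuracy    = (Tp + Tn) / Sumd
    recall/TPR  = Tp / (Tp + Fn)
    precision   = Tp / (Tp + Fp)
    FPR         = Fp / (Fp + Tn)
    specificity = Tn / (Fp + Tn)
    F1          = 2·precision·recall / (precision + recall)

all reported as percentages.  The macro average is the arithmetic mean over
classes; mAP here is the macro-averaged precision of argmax decisions (not
a ranked-retrieval integral).  PR curves carry the balance point (BEP)
where precision equals recall — the F1 value there equals that common
value — and ROC curves carry trapezoidal AUC with macro (per-class mean on
a common FPR grid) and micro (pooled one-vs-rest) averages.

Zero-denominator rates are reported as 0 and flagged rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "CurveSeries",
    "confusion_matrix",
    "class_metrics",
    "macro_average",
    "micro_accuracy",
    "mean_average_precision",
    "pr_curve",
    "roc_curve",
    "macro_roc",
    "micro_roc",
    "metric_report",
    "round2",
]


def round2(x: float) -> float:
    """Half-up rounding to two decimals (the convention used in reports)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))


# -- confusion matrix --------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """K×K counts; rows are true classes, columns predictions."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError(f"confusion matrix must be square, got {c.shape}")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("confusion matrix must hold non-negative integers")
        self.counts = c.astype(np.int64)

    @property
    def num_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        """Sumd: the number of evaluated clips."""
        return int(self.counts.sum())

    def one_vs_rest(self, k: int) -> tuple[int, int, int, int]:
        """(Tp, Tn, Fp, Fn) for class k."""
        c = self.counts
        tp = int(c[k, k])
        fn = int(c[k].sum()) - tp
        fp = int(c[:, k].sum()) - tp
        tn = self.total - tp - fn - fp
        return tp, tn, fp, fn


def confusion_matrix(y_true, y_pred, num_classes: int) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("label vectors must be 1-D and equal length")
    for name, arr in (("true", y_true), ("predicted", y_pred)):
        bad = np.flatnonzero((arr < 0) | (arr >= num_classes))
        if bad.size:
            raise ValueError(
                f"{name} label {arr[bad[0]]} at index {bad[0]} outside 0..{num_classes - 1}"
            )
    counts = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


# -- per-class and averaged metrics ------------------------------------------


@dataclass
class ClassMetrics:
    """One-vs-rest rates for a single class (or an average), as percentages."""

    accuracy: float
    precision: float
    recall: float
    fpr: float
    specificity: float
    f1: float
    degenerate: bool = False  # any zero-denominator rate was forced to 0

    def as_dict(self, rounded: bool = True) -> dict:
        f = round2 if rounded else float
        return {
            "accuracy": f(self.accuracy),
            "precision": f(self.precision),
            "recall": f(self.recall),
            "fpr": f(self.fpr),
            "specificity": f(self.specificity),
            "f1": f(self.f1),
        }


def _rate(num: float, den: float) -> tuple[float, bool]:
    return (0.0, True) if den == 0 else (100.0 * num / den, False)


def class_metrics(cm: ConfusionMatrix, k: int) -> ClassMetrics:
    tp, tn, fp, fn = cm.one_vs_rest(k)
    acc, d0 = _rate(tp + tn, cm.total)
    rec, d1 = _rate(tp, tp + fn)
    prec, d2 = _rate(tp, tp + fp)
    fpr, d3 = _rate(fp, fp + tn)
    spec, d4 = _rate(tn, fp + tn)
    if prec + rec > 0:
        f1, d5 = f1_score(prec, rec), False
    else:
        f1, d5 = 0.0, True
    return ClassMetrics(acc, prec, rec, fpr, spec, f1, any((d0, d1, d2, d3, d4, d5)))


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (both on the same scale)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def macro_average(per_class: list[ClassMetrics]) -> ClassMetrics:
    if not per_class:
        raise ValueError("need at least one class")
    mean = lambda vals: float(np.mean(vals))  # noqa: E731
    return ClassMetrics(
        accuracy=mean([m.accuracy for m in per_class]),
        precision=mean([m.precision for m in per_class]),
        recall=mean([m.recall for m in per_class]),
        fpr=mean([m.fpr for m in per_class]),
        specificity=mean([m.specificity for m in per_class]),
        f1=mean([m.f1 for m in per_class]),
        degenerate=any(m.degenerate for m in per_class),
    )


def micro_accuracy(cm: ConfusionMatrix) -> float:
    """Trace over total, as a percentage."""
    if cm.total == 0:
        return 0.0
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def mean_average_precision(cm: ConfusionMatrix) -> float:
    """mAP: macro average of per-class precision at argmax decisions."""
    per_class = [class_metrics(cm, k) for k in range(cm.num_classes)]
    return macro_average(per_class).precision


# -- threshold-swept curves --------------------------------------------------


@dataclass
class CurveSeries:
    """Threshold sweep of a binary score: (x, y) points plus summaries."""

    x: np.ndarray
    y: np.ndarray
    thresholds: np.ndarray
    auc: float | None = None
    bep: float | None = None  # PR curves: the precision=recall value
    degenerate: bool = False

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.x.tolist(), self.y.tolist()))


def _binary_counts(scores: np.ndarray, labels: np.ndarray):
    """Cumulative Tp/Fp over scores sorted descending, one row per distinct
    threshold (ties collapsed)."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    pos = labels[order].astype(np.float64)
    tp = np.cumsum(pos)
    fp = np.cumsum(1.0 - pos)
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    return s[distinct], tp[distinct], fp[distinct]


def pr_curve(scores, labels) -> CurveSeries:
    """Precision/recall at every distinct threshold, with the balance point.

    ``labels`` are binary (1 = the class of interest).  The BEP is located
    where |precision − recall| is minimal, linearly interpolated between the
    two bracketing thresholds; F1 at the BEP equals the common value.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    npos = int(labels.sum())
    if npos == 0 or npos == labels.size:
        return CurveSeries(
            x=np.zeros(0), y=np.zeros(0), thresholds=np.zeros(0), degenerate=True
        )
    thr, tp, fp = _binary_counts(scores, labels)
    recall = tp / npos
    precision = tp / (tp + fp)
    diff = precision - recall
    i = int(np.argmin(np.abs(diff)))
    bep = float(precision[i])
    # refine by linear interpolation across the nearest sign change
    sign_change = np.flatnonzero(np.diff(np.sign(diff)) != 0)
    if sign_change.size:
        j = sign_change[np.argmin(np.abs(sign_change - i))]
        d0, d1 = diff[j], diff[j + 1]
        if d0 != d1:
            t = d0 / (d0 - d1)
            bep = float(precision[j] + t * (precision[j + 1] - precision[j]))
    return CurveSeries(x=recall, y=precision, thresholds=thr, bep=bep)


def roc_curve(scores, labels) -> CurveSeries:
    """FPR/TPR sweep from (0,0) to (1,1) with trapezoidal AUC."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    npos = int(labels.sum())
    nneg = labels.size - npos
    if npos == 0 or nneg == 0:
        return CurveSeries(
            x=np.zeros(0), y=np.zeros(0), thresholds=np.zeros(0), degenerate=True
        )
    thr, tp, fp = _binary_counts(scores, labels)
    tpr = np.r_[0.0, tp / npos]
    fpr = np.r_[0.0, fp / nneg]
    auc = float(np.trapezoid(tpr, fpr))
    return CurveSeries(x=fpr, y=tpr, thresholds=np.r_[np.inf, thr], auc=auc)


def macro_roc(
    score_matrix: np.ndarray, labels: np.ndarray, grid_size: int = 101
) -> CurveSeries:
    """Macro-averaged ROC: mean of per-class curves on a common FPR grid."""
    score_matrix = np.asarray(score_matrix, dtype=np.float64)
    labels = np.asarray(labels)
    k = score_matrix.shape[1]
    grid = np.linspace(0.0, 1.0, grid_size)
    tprs = []
    for c in range(k):
        curve = roc_curve(score_matrix[:, c], (labels == c).astype(int))
        if curve.degenerate:
            continue
        tprs.append(np.interp(grid, curve.x, curve.y))
    if not tprs:
        return CurveSeries(
            x=grid, y=np.zeros_like(grid), thresholds=np.zeros(0), degenerate=True
        )
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[0] = 0.0
    auc = float(np.trapezoid(mean_tpr, grid))
    return CurveSeries(x=grid, y=mean_tpr, thresholds=np.zeros(0), auc=auc)


def micro_roc(score_matrix: np.ndarray, labels: np.ndarray) -> CurveSeries:
    """Micro-averaged ROC: pool every (clip, class) one-vs-rest decision."""
    score_matrix = np.asarray(score_matrix, dtype=np.float64)
    labels = np.asarray(labels)
    n, k = score_matrix.shape
    onehot = np.zeros((n, k), dtype=int)
    onehot[np.arange(n), labels] = 1
    return roc_curve(score_matrix.ravel(), onehot.ravel())


# -- aggregate report --------------------------------------------------------


@dataclass
class MetricReport:
    class_names: list[str]
    cm: ConfusionMatrix
    per_class: list[ClassMetrics]
    macro: ClassMetrics
    micro_accuracy: float
    map_score: float
    pr: dict = field(default_factory=dict)
    roc: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "class_names": list(self.class_names),
            "confusion_matrix": self.cm.counts.tolist(),
            "per_class": {
                name: m.as_dict()
                for name, m in zip(self.class_names, self.per_class)
            },
            "macro": self.macro.as_dict(),
            "micro_accuracy": round2(self.micro_accuracy),
            "mAP": round2(self.map_score),
        }
        if self.roc:
            d["auc"] = {
                name: (None if c.degenerate else round(c.auc, 4))
                for name, c in self.roc.items()
            }
        if self.pr:
            d["bep"] = {
                name: (None if c.degenerate else round(c.bep, 4))
                for name, c in self.pr.items()
            }
        return d


def metric_report(
    y_true,
    y_pred,
    class_names: list[str],
    score_matrix: np.ndarray | None = None,
) -> MetricReport:
    """Full evaluation: confusion matrix, per-class + macro metrics, and —
    when per-class probability scores are given — PR/ROC curve families with
    macro/micro ROC averages."""
    k = len(class_names)
    cm = confusion_matrix(y_true, y_pred, k)
    per_class = [class_metrics(cm, i) for i in range(k)]
    report = MetricReport(
        class_names=list(class_names),
        cm=cm,
        per_class=per_class,
        macro=macro_average(per_class),
        micro_accuracy=micro_accuracy(cm),
        map_score=mean_average_precision(cm),
    )
    if score_matrix is not None:
        score_matrix = np.asarray(score_matrix, dtype=np.float64)
        labels = np.asarray(y_true)
        for i, name in enumerate(class_names):
            binary = (labels == i).astype(int)
            report.pr[name] = pr_curve(score_matrix[:, i], binary)
            report.roc[name] = roc_curve(score_matrix[:, i], binary)
        report.roc["macro"] = macro_roc(score_matrix, labels)
        report.roc["micro"] = micro_roc(score_matrix, labels)
    return report
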