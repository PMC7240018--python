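"""Classifier evaluation battery.

Per-simulation confusion matrices (rows = predicted class, columns =
actual class), one-vs-rest class metrics (accuracy, sensitivity,
specificity, precision, F-score), total accuracy, per-class ROC curves
with AUC, the mean ROC over repeated simulations (mean true-positive
rate on a fixed false-positive-rate grid), and Shapiro-Wilk normality
testing of per-simulation metric values.

Two summary accuracies are reported: ``total_accuracy`` — the overall
fraction of correctly classified frames (trace / total) — and
``mean_class_accuracy`` — the mean of the four one-vs-rest class
accuracies.  They differ whenever errors are unevenly spread.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _sk_roc_curve

logger = logging.getLogger(__name__)

DEFAULT_CLASSES = (1, 2, 3, 4)
FPR_GRID = np.linspace(0.0, 1.0, 1001)
METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f_score")


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest counts and derived metrics for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_score: float


@dataclass(frozen=True)
class ROCCurve:
    """One-vs-rest ROC: FPR/TPR staircase from (0,0) to (1,1), plus AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class EvalReport:
    """Everything measured on one train/test simulation."""

    confusion: np.ndarray                 # (k, k), rows predicted, cols actual
    classes: tuple
    per_class: dict = field(default_factory=dict)     # class -> ClassMetrics
    roc: dict = field(default_factory=dict)           # class -> ROCCurve
    total_accuracy: float = 0.0
    mean_class_accuracy: float = 0.0


def confusion_matrix(y_true, y_pred, classes=DEFAULT_CLASSES) -> np.ndarray:
    """Count matrix with rows = predicted class, columns = actual class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    if len(y_true) == 0:
        raise ValueError("cannot build a confusion matrix from no frames")
    index = {c: i for i, c in enumerate(classes)}
    bad = (set(np.unique(y_true)) | set(np.unique(y_pred))) - set(classes)
    if bad:
        raise ValueError(f"labels outside {tuple(classes)}: {sorted(bad)}")
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[p], index[t]] += 1
    return cm


def _safe_div(num, den, what: str) -> float:
    if den == 0:
        logger.info("zero denominator for %s; defined as 0", what)
        return 0.0
    return num / den


def class_metrics(cm: np.ndarray, cls, classes=DEFAULT_CLASSES) -> ClassMetrics:
    """One-vs-rest reduction of the confusion matrix for one class."""
    cm = np.asarray(cm)
    total = int(cm.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    c = list(classes).index(cls)
    tp = int(cm[c, c])
    fp = int(cm[c, :].sum()) - tp      # predicted c, actually other
    fn = int(cm[:, c].sum()) - tp      # actually c, predicted other
    tn = total - tp - fp - fn
    precision = _safe_div(tp, tp + fp, f"precision(class {cls})")
    recall = _safe_div(tp, tp + fn, f"sensitivity(class {cls})")
    return ClassMetrics(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=(tp + tn) / total,
        sensitivity=recall,
        specificity=_safe_div(tn, tn + fp, f"specificity(class {cls})"),
        precision=precision,
        f_score=_safe_div(2 * precision * recall, precision + recall,
                          f"f_score(class {cls})"),
    )


def total_accuracy(cm: np.ndarray) -> float:
    """Overall fraction of correctly classified frames: trace / total."""
    cm = np.asarray(cm)
    return float(np.trace(cm) / cm.sum())


def mean_class_accuracy(cm: np.ndarray, classes=DEFAULT_CLASSES) -> float:
    """Mean of the per-class one-vs-rest accuracies."""
    return float(np.mean([class_metrics(cm, c, classes).accuracy for c in classes]))


def roc_curve(y_true, scores, cls) -> ROCCurve:
    """One-vs-rest ROC for one class from its probability column.

    Thresholds sweep every distinct score (exact curve); AUC by the
    trapezoidal rule.  Raises if the ground truth contains only one of
    positive/negative.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = y_true == cls
    if pos.all() or not pos.any():
        raise ValueError(f"ROC undefined: class {cls!r} needs both positives "
                         "and negatives in the ground truth")
    fpr, tpr, _ = _sk_roc_curve(pos.astype(int), scores)
    return ROCCurve(fpr=fpr, tpr=tpr, auc=float(_auc(fpr, tpr)))


def interp_roc(curve: ROCCurve, grid=FPR_GRID) -> np.ndarray:
    """TPR of the (linearly interpolated) curve at each grid FPR."""
    # collapse duplicate FPR values to their best TPR so np.interp sees
    # a strictly usable staircase
    fpr, tpr = curve.fpr, curve.tpr
    uniq, idx = np.unique(fpr[::-1], return_index=True)
    best_tpr = tpr[::-1][idx]
    return np.interp(grid, uniq, best_tpr)


def mean_roc(curves, grid=FPR_GRID) -> ROCCurve:
    """Pointwise-mean ROC: mean TPR at each FPR on a fixed grid."""
    curves = list(curves)
    if not curves:
        raise ValueError("need at least one ROC curve")
    grid = np.asarray(grid, dtype=float)
    tprs = np.stack([interp_roc(c, grid) for c in curves])
    mean_tpr = tprs.mean(axis=0)
    return ROCCurve(fpr=grid, tpr=mean_tpr, auc=float(_auc(grid, mean_tpr)))


def normality_test(values) -> tuple[float, float]:
    """Shapiro-Wilk test of normality; returns (W, p).

    Used on the per-simulation metric values before reporting means;
    3 <= n <= 5000 and non-constant input required.
    """
    values = np.asarray(values, dtype=float)
    if not 3 <= len(values) <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3..5000 values, got {len(values)}")
    if np.ptp(values) == 0:
        raise ValueError("Shapiro-Wilk is undefined for constant input")
    w, p = stats.shapiro(values)
    return float(w), float(p)


def evaluate_predictions(y_true, y_pred, probs=None,
                         classes=DEFAULT_CLASSES) -> EvalReport:
    """Build a full :class:`EvalReport` for one simulation."""
    classes = tuple(classes)
    cm = confusion_matrix(y_true, y_pred, classes)
    report = EvalReport(confusion=cm, classes=classes,
                        total_accuracy=total_accuracy(cm),
                        mean_class_accuracy=mean_class_accuracy(cm, classes))
    for c in classes:
        report.per_class[c] = class_metrics(cm, c, classes)
    if probs is not None:
        probs = np.asarray(probs, dtype=float)
        y_true = np.asarray(y_true)
        for i, c in enumerate(classes):
            if (y_true == c).any() and (y_true != c).any():
                report.roc[c] = roc_curve(y_true, probs[:, i], c)
    return report


def summarize(reports) -> dict:
    """Mean +/- SD of every metric over simulations, plus mean structures.

    Returns a dict with ``total_accuracy``/``mean_class_accuracy``
    (mean, sd), per-class metric (mean, sd) pairs, the elementwise mean
    confusion matrix, per-class mean ROC curves and their AUCs, and
    Shapiro-Wilk p-values of the per-simulation total accuracies where
    computable.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("need at least one report")
    classes = reports[0].classes
    totals = np.array([r.total_accuracy for r in reports])
    means = np.array([r.mean_class_accuracy for r in reports])
    out = {
        "n_simulations": len(reports),
        "classes": classes,
        "total_accuracy": (float(totals.mean()), float(totals.std(ddof=1) if len(totals) > 1 else 0.0)),
        "mean_class_accuracy": (float(means.mean()), float(means.std(ddof=1) if len(means) > 1 else 0.0)),
        "mean_confusion": np.mean([r.confusion for r in reports], axis=0),
        "per_class": {},
        "mean_roc": {},
        "auc": {},
    }
    for c in classes:
        out["per_class"][c] = {}
        for m in METRIC_NAMES:
            vals = np.array([getattr(r.per_class[c], m) for r in reports])
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            out["per_class"][c][m] = (float(vals.mean()), sd)
        curves = [r.roc[c] for r in reports if c in r.roc]
        if curves:
            mc = mean_roc(curves)
            out["mean_roc"][c] = mc
            out["auc"][c] = mc.auc
    if len(totals) >= 3 and np.ptp(totals) > 0:
        out["shapiro_total_accuracy"] = normality_test(totals)
    return out


def plot_roc(curves_by_class: dict, path=None, ax=None):
    """Plot per-class (mean) ROC curves; requires matplotlib."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for cls, curve in curves_by_class.items():
        ax.plot(curve.fpr, curve.tpr,
                label=f"class {cls} (AUC {100 * curve.auc:.1f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate (1 − specificity)")
    ax.set_ylabel("true positive rate (sensitivity)")
    ax.legend(loc="lower right", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def dataset_summary(class_counts: dict) -> dict:
    """Database arithmetic: per-class counts, total, and proportions."""
    counts = {int(k): int(v) for k, v in class_counts.items()}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty dataset")
    return {
        "class_counts": counts,
        "total": total,
        "proportions": {c: n / total for c, n in counts.items()},
    }
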