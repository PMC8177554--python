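"""Confusion-matrix metrics and Cohen's kappa, per class and macro.

For each class the multiclass predictions are binarized one-vs-rest and
summarized by the binary confusion counts, from which::

    accuracy     = (TP + TN) / (TP + TN + FP + FN)
    sensitivity  = TP / (TP + FN)
    specificity  = TN / (TN + FP)
    F1           = 2 TP / (2 TP + FP + FN)
    kappa        = (Po − Pe) / (1 − Pe)

with Po the fractional accuracy and the chance agreement::

    Pe = [(TP+FP)(TP+FN) + (TN+FN)(TN+FP)] / (TP+TN+FP+FN)²

The overall summary is the unweighted macro mean over classes.  This
aggregation explains overall accuracy sitting far above overall
sensitivity under class imbalance (many true negatives per class); a
micro-averaged variant is available for comparison.  Percentages are
reported on the 0–100 scale; kappa, a chance-corrected agreement, is also
scaled to percent in reports (so it spans −100…100).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "f1", "kappa")


@dataclass
class ConfusionCounts:
    """Binary one-vs-rest confusion counts for one positive class."""

    tp: int
    tn: int
    fp: int
    fn: int
    class_label: str = ""

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(y_true, y_pred, positive_class) -> ConfusionCounts:
    """Binarize both label vectors against ``positive_class`` and count."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} vs {y_pred.shape}"
        )
    if y_true.size < 1:
        raise ValueError("empty label vectors")
    t = y_true == positive_class
    p = y_pred == positive_class
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
        class_label=str(positive_class),
    )


def _safe_ratio(num: float, den: float, name: str, label: str) -> float:
    if den == 0:
        logger.info("degenerate %s for class %s: 0/0 set to 0", name, label)
        return 0.0
    return num / den


def binary_metrics(c: ConfusionCounts) -> dict:
    """Accuracy/sensitivity/specificity/F1 in percent (0/0 ratios → 0)."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    return {
        "accuracy": 100.0 * (c.tp + c.tn) / c.total,
        "sensitivity": 100.0 * _safe_ratio(c.tp, c.tp + c.fn,
                                           "sensitivity", c.class_label),
        "specificity": 100.0 * _safe_ratio(c.tn, c.tn + c.fp,
                                           "specificity", c.class_label),
        "f1": 100.0 * _safe_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn,
                                  "f1", c.class_label),
    }


def kappa(c: ConfusionCounts) -> float:
    """Cohen's kappa (as a coefficient, not percent)."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    po = (c.tp + c.tn) / c.total
    pe = (
        (c.tp + c.fp) * (c.tp + c.fn) + (c.tn + c.fn) * (c.tn + c.fp)
    ) / c.total**2
    if pe == 1.0:
        raise ValueError("chance agreement saturated (Pe = 1)")
    return (po - pe) / (1.0 - pe)


@dataclass
class MetricReport:
    """Per-class and macro-averaged metrics (percent scale)."""

    class_order: tuple
    per_class: dict      # class -> {metric: percent}
    macro: dict          # metric -> percent
    confusion: np.ndarray  # raw k×k matrix, rows = true, cols = predicted

    def to_dict(self) -> dict:
        return {
            "class_order": list(self.class_order),
            "per_class": {k: dict(v) for k, v in self.per_class.items()},
            "macro": dict(self.macro),
            "confusion": self.confusion.tolist(),
        }


def macro_report(y_true, y_pred, class_order) -> MetricReport:
    """One-vs-rest metrics per class plus their unweighted macro mean."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    known = set(class_order)
    unknown = (set(np.unique(y_true)) | set(np.unique(y_pred))) - known
    if unknown:
        raise ValueError(f"labels outside class order: {sorted(unknown)}")
    per_class = {}
    for label in class_order:
        c = confusion_counts(y_true, y_pred, label)
        vals = binary_metrics(c)
        vals["kappa"] = 100.0 * kappa(c)
        per_class[label] = vals
    macro = {
        name: float(np.mean([per_class[lb][name] for lb in class_order]))
        for name in METRIC_NAMES
    }
    k = len(class_order)
    index = {label: i for i, label in enumerate(class_order)}
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        confusion[index[t], index[p]] += 1
    return MetricReport(
        class_order=tuple(class_order),
        per_class=per_class,
        macro=macro,
        confusion=confusion,
    )


def micro_report(y_true, y_pred, class_order) -> dict:
    """Micro-averaged variant: counts pooled over classes before the ratios."""
    pooled = ConfusionCounts(0, 0, 0, 0, "micro")
    for label in class_order:
        c = confusion_counts(y_true, y_pred, label)
        pooled.tp += c.tp
        pooled.tn += c.tn
        pooled.fp += c.fp
        pooled.fn += c.fn
    vals = binary_metrics(pooled)
    vals["kappa"] = 100.0 * kappa(pooled)
    return vals
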