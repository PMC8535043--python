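"""Binary-classification metrics in the workflow's closed forms.

Sensitivity (TPR) = TP/(TP+FN); specificity (TNR) = TN/(TN+FP); the AUC is
the closed form from hard predictions, AUC = (1 + TPR - FPR)/2, which equals
the balanced accuracy of a single operating point.  A 0/0 rate is defined as
0 and warned about (possible at very small fold sizes).  Report rounding is
two decimals, half away from zero, matching conventional table formatting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion",
    "sensitivity",
    "specificity",
    "accuracy",
    "auc_from_rates",
    "round_half_away",
    "ClassReport",
    "class_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Counts with label 1 as the positive class."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _rate(num: int, den: int, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} is 0/0; returning 0", stacklevel=3)
        return 0.0
    return num / den


def sensitivity(cc: ConfusionCounts) -> float:
    return _rate(cc.tp, cc.tp + cc.fn, "sensitivity")


def specificity(cc: ConfusionCounts) -> float:
    return _rate(cc.tn, cc.tn + cc.fp, "specificity")


def accuracy(cc: ConfusionCounts) -> float:
    return _rate(cc.tp + cc.tn, cc.n, "accuracy")


def auc_from_rates(tpr: float, fpr: float) -> float:
    """AUC of the single-point ROC: (1 + TPR - FPR) / 2."""
    if not (0 <= tpr <= 1 and 0 <= fpr <= 1):
        raise ValueError("tpr and fpr must lie in [0, 1]")
    return (1.0 + tpr - fpr) / 2.0


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (0.905 -> 0.91), unlike banker's rounding.

    The value is first quantized at 10 decimals so that binary float error
    (e.g. 0.88 - 0.07 = 0.9049999...) does not flip a true half-point down.
    """
    d = Decimal(repr(float(x))).quantize(Decimal("1e-10"), rounding=ROUND_HALF_UP)
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ClassReport:
    """Per-class precision/recall/f1/support plus the usual averages."""

    classes: list[int]
    precision: dict[int, float]
    recall: dict[int, float]
    f1: dict[int, float]
    support: dict[int, int]
    accuracy: float
    macro_avg: dict[str, float]
    weighted_avg: dict[str, float]

    def to_dict(self) -> dict:
        rows = {
            str(float(c)): {
                "precision": self.precision[c],
                "recall": self.recall[c],
                "f1-score": self.f1[c],
                "support": self.support[c],
            }
            for c in self.classes
        }
        rows["accuracy"] = self.accuracy
        rows["macro avg"] = dict(self.macro_avg)
        rows["weighted avg"] = dict(self.weighted_avg)
        return rows


def _f1(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def class_report(y_true, y_pred) -> ClassReport:
    """Per-class precision = TP/(TP+FP), recall = TP/(TP+FN), harmonic f1,
    with macro (unweighted) and support-weighted averages."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    classes = sorted(set(y_true) | set(y_pred))
    precision, recall, f1, support = {}, {}, {}, {}
    for c in classes:
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        precision[c] = _rate(tp, tp + fp, f"precision[{c}]")
        recall[c] = _rate(tp, tp + fn, f"recall[{c}]")
        f1[c] = _f1(precision[c], recall[c])
        support[c] = int(np.sum(y_true == c))
    n = len(y_true)
    acc = float(np.mean(y_true == y_pred))
    macro = {
        "precision": float(np.mean([precision[c] for c in classes])),
        "recall": float(np.mean([recall[c] for c in classes])),
        "f1-score": float(np.mean([f1[c] for c in classes])),
        "support": n,
    }
    weighted = {
        "precision": float(sum(precision[c] * support[c] for c in classes) / n),
        "recall": float(sum(recall[c] * support[c] for c in classes) / n),
        "f1-score": float(sum(f1[c] * support[c] for c in classes) / n),
        "support": n,
    }
    return ClassReport(classes, precision, recall, f1, support, acc, macro, weighted)
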