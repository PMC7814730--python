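"""Classification metrics computed from explicit confusion matrices.

Balanced accuracy = (sensitivity + specificity) / 2, i.e.
(TP/(TP+FN) + TN/(TN+FP)) / 2 — the primary evaluation metric; alert
precision TP/(TP+FP) lives in the alert-evaluation module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined because a class is absent."""


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must have equal length")
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


def sensitivity(cm: ConfusionMatrix) -> float:
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("no positive samples: sensitivity undefined")
    return cm.tp / (cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float:
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("no negative samples: specificity undefined")
    return cm.tn / (cm.tn + cm.fp)


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """Mean of sensitivity and specificity; errors if a class is absent."""
    return (sensitivity(cm) + specificity(cm)) / 2.0


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 by convention on degenerate margins."""
    denom = math.sqrt(
        float(cm.tp + cm.fp)
        * float(cm.tp + cm.fn)
        * float(cm.tn + cm.fp)
        * float(cm.tn + cm.fn)
    )
    if denom == 0:
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / denom
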