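"""Confusion-matrix evaluation: classification accuracy, recall, precision.

Rates are kept as proportions internally; percentage formatting belongs to
the reporting layer. A rate whose denominator is zero is reported as
``None`` (absent), never silently as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = ["ConfusionMatrix", "ClassificationRates", "confusion", "classification_metrics"]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int
    positive_class: str

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def complement(self) -> "ConfusionMatrix":
        """The same predictions scored with the other class as positive."""
        return ConfusionMatrix(
            tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp,
            positive_class=f"not-{self.positive_class}",
        )


class ClassificationRates(NamedTuple):
    accuracy: float
    recall: float | None
    precision: float | None


def confusion(
    predicted: Sequence, truth: Sequence, positive_class: str
) -> ConfusionMatrix:
    """Count TP/FP/FN/TN of predictions against truth."""
    pred = np.asarray(predicted, dtype=object)
    true = np.asarray(truth, dtype=object)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    pp = pred == positive_class
    tp = true == positive_class
    return ConfusionMatrix(
        tp=int(np.sum(pp & tp)),
        fp=int(np.sum(pp & ~tp)),
        fn=int(np.sum(~pp & tp)),
        tn=int(np.sum(~pp & ~tp)),
        positive_class=positive_class,
    )


def classification_metrics(cm: ConfusionMatrix) -> ClassificationRates:
    """Accuracy (TP+TN)/total, recall TP/(TP+FN), precision TP/(TP+FP).

    Recall is ``None`` when no true positives exist to recall
    (TP+FN = 0); precision is ``None`` when nothing was predicted
    positive (TP+FP = 0).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    recall = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else None
    precision = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) > 0 else None
    return ClassificationRates(
        accuracy=(cm.tp + cm.tn) / cm.total,
        recall=recall,
        precision=precision,
    )
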