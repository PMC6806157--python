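"""Confusion counts and the binary classification metrics.

Positive class 1 = "virus".  precision = TP/(TP+FP), recall = TP/(TP+FN),
accuracy = (TP+TN)/n.  A zero denominator raises UndefinedMetricError
rather than silently returning 0 — accuracy is a trustworthy summary only
on balanced data, and degenerate denominators on unbalanced synthetic runs
must surface, not hide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class UndefinedMetricError(ZeroDivisionError):
    """The metric's denominator is zero, so the ratio is undefined."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def confusion(predictions, truth) -> ConfusionCounts:
    """Count TP/FP/FN/TN for binary predictions against binary truth."""
    pred = np.asarray(predictions, dtype=np.int64)
    true = np.asarray(truth, dtype=np.int64)
    if pred.shape != true.shape or pred.ndim != 1 or pred.size == 0:
        raise ValueError("predictions and truth must be equal-length 1D, n >= 1")
    if not (np.isin(pred, (0, 1)).all() and np.isin(true, (0, 1)).all()):
        raise ValueError("predictions and truth must be binary (0/1)")
    return ConfusionCounts(
        TP=int(((pred == 1) & (true == 1)).sum()),
        FP=int(((pred == 1) & (true == 0)).sum()),
        FN=int(((pred == 0) & (true == 1)).sum()),
        TN=int(((pred == 0) & (true == 0)).sum()),
    )


def precision(c: ConfusionCounts) -> float:
    if c.TP + c.FP == 0:
        raise UndefinedMetricError("precision undefined: no positive predictions")
    return c.TP / (c.TP + c.FP)


def recall(c: ConfusionCounts) -> float:
    if c.TP + c.FN == 0:
        raise UndefinedMetricError("recall undefined: no positive ground truth")
    return c.TP / (c.TP + c.FN)


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined: no samples")
    return (c.TP + c.TN) / c.total


def report(c: ConfusionCounts) -> dict:
    """Counts plus the three metrics, for CSV/JSON evaluation output."""
    return {
        "TP": c.TP,
        "FP": c.FP,
        "FN": c.FN,
        "TN": c.TN,
        "precision": precision(c),
        "recall": recall(c),
        "accuracy": accuracy(c),
    }
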