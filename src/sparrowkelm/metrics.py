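"""Confusion-matrix metrics used as CV fitness and for reporting."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "MetricSet", "confusion", "compute_metrics"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricSet:
    acc: float
    sensitivity: float
    specificity: float
    mcc: float


def confusion(y_true, y_pred, positive_label=1) -> ConfusionCounts:
    """Count TP/TN/FP/FN for binary labels against a given positive label."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} true labels vs {y_pred.shape} predictions"
        )
    values = np.unique(np.concatenate([y_true, y_pred])) if y_true.size else np.array([])
    if values.size > 2:
        raise ValueError(f"labels must be binary, got values {values}")
    pos_t = y_true == positive_label
    pos_p = y_pred == positive_label
    return ConfusionCounts(
        TP=int(np.sum(pos_t & pos_p)),
        TN=int(np.sum(~pos_t & ~pos_p)),
        FP=int(np.sum(~pos_t & pos_p)),
        FN=int(np.sum(pos_t & ~pos_p)),
    )


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """ACC, sensitivity, specificity and MCC of a 2x2 table.

    Degenerate denominators: sensitivity/specificity of an empty class are
    reported as 0 with a warning; MCC with a zero factor under the root is 0.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics of an empty confusion table")
    acc = (c.TP + c.TN) / c.total
    if c.TP + c.FN > 0:
        sens = c.TP / (c.TP + c.FN)
    else:
        warnings.warn("no positive samples; sensitivity reported as 0", stacklevel=2)
        sens = 0.0
    if c.TN + c.FP > 0:
        spec = c.TN / (c.TN + c.FP)
    else:
        warnings.warn("no negative samples; specificity reported as 0", stacklevel=2)
        spec = 0.0
    denom = (
        (c.TN + c.FP) * (c.TN + c.FN) * (c.TP + c.FN) * (c.TP + c.FP)
    )
    if denom > 0:
        mcc = (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom)
    else:
        mcc = 0.0
    return MetricSet(acc=acc, sensitivity=sens, specificity=spec, mcc=mcc)
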