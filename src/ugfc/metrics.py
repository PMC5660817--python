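"""Overlap and success/error metrics between binary masks.

Jaccard R = TP / (TP + FP + FN), Dice D = 2 TP / (2 TP + FP + FN),
sensitivity Se = TP / (TP + FN), specificity Sp = TN / (TN + FP), with TN
counted over the full image grid.  Metrics with a zero denominator are
reported as undefined (None), never as exceptions or silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputDomainError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsRecord:
    """Overlap scores; None marks an undefined (0/0) metric."""

    dice: float | None
    jaccard: float | None
    sensitivity: float | None
    specificity: float | None
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        return {
            "dice": self.dice,
            "jaccard": self.jaccard,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "tn": self.counts.tn,
        }


def confusion_counts(truth: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    """Pixelwise 2x2 table over the full image domain."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise InputDomainError(
            f"mask shapes differ: {truth.shape} vs {pred.shape}")
    for name, m in (("truth", truth), ("pred", pred)):
        if not np.isin(m, (0, 1)).all():
            raise InputDomainError(f"{name} mask must be binary 0/1")
    t = truth.astype(bool)
    s = pred.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(t & s)),
        fp=int(np.sum(~t & s)),
        fn=int(np.sum(t & ~s)),
        tn=int(np.sum(~t & ~s)),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def overlap_metrics(counts: ConfusionCounts) -> MetricsRecord:
    """Dice, Jaccard, sensitivity and specificity from a 2x2 table."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    return MetricsRecord(
        dice=_ratio(2 * tp, 2 * tp + fp + fn),
        jaccard=_ratio(tp, tp + fp + fn),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        counts=counts,
    )


def evaluate_masks(truth: np.ndarray, pred: np.ndarray) -> MetricsRecord:
    """Convenience: counts + metrics in one call."""
    return overlap_metrics(confusion_counts(truth, pred))
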