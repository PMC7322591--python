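"""Screening metrics: confusion counts, accuracy/sensitivity/specificity, ROC/AUC.

Positive = referable (grade >= 2).  A probability equal to the operating
threshold counts as positive.  AUC is the area under the ROC curve by
trapezoidal integration, which with midrank tie handling equals the
Mann-Whitney pairwise concordance P(score_pos > score_neg) + 0.5 P(tie).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .errors import DataError, UndefinedMetricError

__all__ = ["ConfusionCounts", "EvalReport", "confusion", "metrics", "roc_auc", "evaluate"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class EvalReport:
    """Accuracy/sensitivity/specificity as percentages, AUC as a fraction."""

    accuracy: float
    sensitivity: float
    specificity: float
    auc: float | None
    threshold: float
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        with open(Path(path), "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def format_table(self) -> str:
        auc = f"{self.auc:.2f}" if self.auc is not None else "n/a"
        return (
            "Accuracy (%)  Sensitivity (%)  Specificity (%)  AUC\n"
            f"{self.accuracy:12.2f}  {self.sensitivity:15.2f}  "
            f"{self.specificity:15.2f}  {auc}"
        )


def _check_pairs(labels, probabilities):
    y = np.asarray(labels).ravel()
    p = np.asarray(probabilities, dtype=np.float64).ravel()
    if y.size != p.size:
        raise DataError(f"{y.size} labels but {p.size} probabilities")
    if y.size == 0:
        raise DataError("empty evaluation set")
    y = y.astype(np.float64)
    if not np.isin(y, (0.0, 1.0)).all():
        raise DataError("labels must be binary 0/1")
    return y.astype(int), p


def confusion(labels, probabilities, threshold: float = 0.5) -> ConfusionCounts:
    """Count TP/FP/TN/FN comparing ``probability >= threshold`` to the label."""
    y, p = _check_pairs(labels, probabilities)
    pred = p >= threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def metrics(counts: ConfusionCounts, threshold: float = 0.5) -> EvalReport:
    """Accuracy, sensitivity and specificity (percent) from confusion counts.

    Raises :class:`UndefinedMetricError` instead of returning silent NaN when
    a denominator class is empty.
    """
    if counts.total == 0:
        raise UndefinedMetricError("no evaluated records")
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive records")
    if counts.tn + counts.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative records")
    return EvalReport(
        accuracy=100.0 * (counts.tp + counts.tn) / counts.total,
        sensitivity=100.0 * counts.tp / (counts.tp + counts.fn),
        specificity=100.0 * counts.tn / (counts.tn + counts.fp),
        auc=None,
        threshold=threshold,
        counts=counts,
    )


def roc_auc(labels, probabilities) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the ROC curve points (FPR, TPR).

    Trapezoidal integration over all score thresholds; equal to the pairwise
    concordance statistic with ties counted 0.5.
    """
    y, p = _check_pairs(labels, probabilities)
    if y.min() == y.max():
        raise DataError("ROC needs both classes present")
    fpr, tpr, _ = _roc_curve(y, p)
    return float(_trapezoid_auc(fpr, tpr)), fpr, tpr


def evaluate(labels, probabilities, threshold: float = 0.5) -> EvalReport:
    """Full screening report: thresholded metrics plus AUC."""
    report = metrics(confusion(labels, probabilities, threshold), threshold)
    auc, _, _ = roc_auc(labels, probabilities)
    return EvalReport(
        accuracy=report.accuracy,
        sensitivity=report.sensitivity,
        specificity=report.specificity,
        auc=auc,
        threshold=threshold,
        counts=report.counts,
    )


def roc_to_csv(labels, probabilities, path: str | Path) -> None:
    """Write the ROC curve points as CSV (columns fpr, tpr) for plotting."""
    _, fpr, tpr = roc_auc(labels, probabilities)
    with open(Path(path), "w") as fh:
        fh.write("fpr,tpr\n")
        for f, t in zip(fpr, tpr):
            fh.write(f"{f:.10g},{t:.10g}\n")
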