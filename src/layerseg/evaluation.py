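"""Segmentation metrics: per-class accuracy, Jaccard index, pairwise comparison.

All metrics are computed from an L×L confusion matrix restricted to pixels
that are foreground in the ground truth.  Per-class accuracy for class i is
``C_ii / sum_j C_ij`` (recall over the truth pixels of i); the Jaccard index
is the intersection over union, ``C_ii / (sum_j C_ij + sum_j C_ji - C_ii)``.
Classes with no truth pixels are reported as NaN and excluded from means.
Method-vs-method comparison counts per-frame wins/losses/ties of the mean
metric and sums the per-frame differentials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "ConfusionMatrix",
    "ComparisonRecord",
    "confusion_matrix",
    "per_class_accuracy",
    "jaccard_index",
    "pairwise_compare",
    "metrics_frame",
]


@dataclass
class ConfusionMatrix:
    """Counts ``C[i, j]`` of pixels with truth label ``labels[i]`` predicted
    as ``labels[j]``, over the truth foreground."""

    counts: np.ndarray
    labels: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ComparisonRecord:
    """Per-frame win/loss/tie counts of method A against method B and the
    summed differential of the per-frame mean metric (same scale as the
    metric passed in)."""

    wins: int
    losses: int
    ties: int
    total_differential: float


def confusion_matrix(truth: np.ndarray, pred: np.ndarray,
                     labels=None) -> ConfusionMatrix:
    """Confusion matrix over pixels that are foreground (nonzero) in truth."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError(
            f"truth shape {truth.shape} != prediction shape {pred.shape}"
        )
    m = truth > 0
    t, p = truth[m], pred[m]
    if labels is None:
        labels = np.unique(np.concatenate([t, p]))
        labels = labels[labels > 0]
    labels = np.asarray(labels)
    counts = _sk_confusion(t, p, labels=labels)
    return ConfusionMatrix(counts, labels)


def per_class_accuracy(C: ConfusionMatrix) -> np.ndarray:
    """``PC_i = C_ii / sum_j C_ij``; NaN where the class has no truth pixels."""
    counts = C.counts.astype(float)
    row = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pc = np.diag(counts) / row
    pc[row == 0] = np.nan
    return pc


def jaccard_index(C: ConfusionMatrix) -> np.ndarray:
    """``JI_i = C_ii / (sum_j C_ij + sum_j C_ji - C_ii)``; NaN when the
    denominator vanishes."""
    counts = C.counts.astype(float)
    diag = np.diag(counts)
    denom = counts.sum(axis=1) + counts.sum(axis=0) - diag
    with np.errstate(invalid="ignore", divide="ignore"):
        ji = diag / denom
    ji[denom == 0] = np.nan
    return ji


def pairwise_compare(means_a, means_b) -> ComparisonRecord:
    """Frame-by-frame comparison of two methods' per-frame mean metrics."""
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("per-frame metric vectors must be 1-D and equal length")
    return ComparisonRecord(
        wins=int(np.sum(a > b)),
        losses=int(np.sum(a < b)),
        ties=int(np.sum(a == b)),
        total_differential=float(np.sum(a - b)),
    )


def metrics_frame(truth: np.ndarray, pred: np.ndarray, labels=None,
                  names: dict | None = None) -> pd.DataFrame:
    """Per-class PC and JI of one frame as a tidy DataFrame."""
    C = confusion_matrix(truth, pred, labels=labels)
    df = pd.DataFrame({
        "label": C.labels,
        "per_class_accuracy": per_class_accuracy(C),
        "jaccard_index": jaccard_index(C),
        "truth_pixels": C.counts.sum(axis=1),
    })
    if names:
        df.insert(1, "name", [names.get(int(l), "") for l in C.labels])
    return df
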