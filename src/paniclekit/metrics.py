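"""Segmentation and trait-agreement metrics.

Pixel metrics (precision, recall, F1, IoU) come from the standard confusion
counts; boundary overlap (BO) is the Jaccard index of the two masks'
edge-pixel sets, which penalizes sloppy outlines that area metrics forgive.
Trait agreement between predicted and measured values is summarized by R²,
RMSE, and relative RMSE (RMSE over the mean measured value, in percent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "AgreementStats",
    "confusion_counts",
    "f1_iou",
    "boundary_pixels",
    "boundary_overlap",
    "agreement",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class AgreementStats:
    r2: float
    rmse: float
    rrmse: float  # percent


def _check_pair(pred: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shapes disagree: {pred.shape} vs {gt.shape}")
    return pred, gt


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Exact pixel counts of prediction/ground-truth overlap."""
    pred, gt = _check_pair(pred, gt)
    return ConfusionCounts(
        tp=int((pred & gt).sum()),
        fp=int((pred & ~gt).sum()),
        fn=int((~pred & gt).sum()),
    )


def f1_iou(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """(precision, recall, F1, IoU) from confusion counts.

    A metric whose denominator is zero is reported as 0, except the fully
    vacuous case TP=FP=FN=0 (two empty masks), which scores 1.0 with a
    warning so batch evaluation never aborts on an empty frame.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp == fp == fn == 0:
        logger.warning("both masks empty; scoring vacuous agreement as 1.0")
        return 1.0, 1.0, 1.0, 1.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    iou = tp / (tp + fp + fn)
    return precision, recall, f1, iou


def boundary_pixels(mask: np.ndarray, connectivity: int = 4) -> set[tuple[int, int]]:
    """Inner-boundary edge set of a mask.

    A foreground pixel is an edge pixel iff at least one of its 4-neighbors
    (8 with ``connectivity=8``) is background or lies outside the frame.
    """
    mask = np.asarray(mask).astype(bool)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    shifts = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        shifts += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    neighbor_bg = np.zeros_like(mask)
    for dr, dc in shifts:
        neighbor_bg |= ~padded[1 + dr:1 + dr + mask.shape[0],
                               1 + dc:1 + dc + mask.shape[1]]
    edge = mask & neighbor_bg
    return set(map(tuple, np.argwhere(edge)))


def boundary_overlap(pred: np.ndarray, gt: np.ndarray,
                     connectivity: int = 4) -> float:
    """Jaccard index of the two masks' edge-pixel sets."""
    pred, gt = _check_pair(pred, gt)
    if not pred.any() and not gt.any():
        logger.warning("both masks empty; boundary overlap vacuously 1.0")
        return 1.0
    ep = boundary_pixels(pred, connectivity)
    eg = boundary_pixels(gt, connectivity)
    union = ep | eg
    if not union:
        return 0.0
    return len(ep & eg) / len(union)


def agreement(predicted: np.ndarray, measured: np.ndarray) -> AgreementStats:
    """R², RMSE, and rRMSE (%) between predicted and measured trait values.

    R² = 1 − SS_res/SS_tot, i.e. agreement with the identity line, not a
    refitted regression; rRMSE = RMSE / mean(measured) × 100.
    """
    predicted = np.asarray(predicted, dtype=float).ravel()
    measured = np.asarray(measured, dtype=float).ravel()
    if predicted.shape != measured.shape:
        raise ValueError("predicted and measured lengths disagree")
    if predicted.size < 2:
        raise ValueError("need at least 2 paired values")
    ss_tot = float(np.sum((measured - measured.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("measured values are all equal; R² undefined")
    mean_measured = float(measured.mean())
    if mean_measured == 0.0:
        raise ValueError("mean of measured values is zero; rRMSE undefined")
    ss_res = float(np.sum((measured - predicted) ** 2))
    rmse = float(np.sqrt(np.mean((predicted - measured) ** 2)))
    return AgreementStats(
        r2=1.0 - ss_res / ss_tot,
        rmse=rmse,
        rrmse=rmse / mean_measured * 100.0,
    )
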