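"""Segmentation evaluation: confusion counts, MPA, MIoU, boundary F1, Ass.

Conventions follow the dichotomous confusion matrix with brain tissue (BT)
as the positive class: rows index the true class, columns the predicted
class, so

    TP = |pred & truth|    FN = |~pred & truth|
    FP = |pred & ~truth|   TN = |~pred & ~truth|

``mpa`` and ``miou`` average the BT and NBT terms exactly as defined for
this pipeline:

    MPA  = (TP/(TP+FP) + TN/(TN+FN)) / 2
    MIoU = (TP/(TP+FP+FN) + TN/(TN+FN+FP)) / 2

Note the MPA terms are precision-like; ``mpa_recall`` provides the
conventional per-class recall average (TP/(TP+FN), TN/(TN+FP)) for users
who want the textbook pixel accuracy — it is never substituted silently.

``mbf`` is the mean boundary-F1 of the two classes with a match tolerance
of 0.75% of the image diagonal, and ``ass`` is the average segmentation
speed N/T in slices per second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .ct_io import as_binary_mask

__all__ = [
    "BOUNDARY_TOLERANCE_FRACTION", "ConfusionCounts", "MetricsReport",
    "confusion", "mpa", "mpa_recall", "miou", "mbf", "ass",
    "boundary_pixels", "boundary_tolerance",
]

#: Fraction of the image diagonal used as the boundary-match tolerance.
BOUNDARY_TOLERANCE_FRACTION = 0.0075


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricsReport:
    MPA: float
    MIoU: float
    MBF: float
    Ass: float
    N: int
    T: float


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel confusion counts of a predicted mask against ground truth."""
    pred = as_binary_mask(pred).astype(bool)
    truth = as_binary_mask(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return ConfusionCounts(
        TP=int(np.sum(pred & truth)),
        FN=int(np.sum(~pred & truth)),
        FP=int(np.sum(pred & ~truth)),
        TN=int(np.sum(~pred & ~truth)),
    )


def mpa(c: ConfusionCounts) -> float:
    """Mean of the BT and NBT accuracy terms TP/(TP+FP) and TN/(TN+FN)."""
    if c.TP + c.FP == 0 or c.TN + c.FN == 0:
        raise ValueError("MPA undefined: empty predicted class")
    return 0.5 * (c.TP / (c.TP + c.FP) + c.TN / (c.TN + c.FN))


def mpa_recall(c: ConfusionCounts) -> float:
    """Conventional mean per-class pixel accuracy (recall form)."""
    if c.TP + c.FN == 0 or c.TN + c.FP == 0:
        raise ValueError("mean recall undefined: empty true class")
    return 0.5 * (c.TP / (c.TP + c.FN) + c.TN / (c.TN + c.FP))


def miou(c: ConfusionCounts) -> float:
    """Mean IoU of the BT and NBT classes."""
    if c.TP + c.FP + c.FN == 0 or c.TN + c.FN + c.FP == 0:
        raise ValueError("MIoU undefined: no pixels in either union")
    return 0.5 * (c.TP / (c.TP + c.FP + c.FN) + c.TN / (c.TN + c.FN + c.FP))


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Boundary of a binary mask: foreground pixels with any 8-neighbor
    background; the image border counts as background."""
    mask = as_binary_mask(mask).astype(bool)
    padded = np.pad(mask, 1, constant_values=False)
    eroded = ndimage.binary_erosion(padded, structure=np.ones((3, 3)))[1:-1, 1:-1]
    return (mask & ~eroded).astype(np.uint8)


def boundary_tolerance(shape: tuple[int, int]) -> float:
    """Match tolerance: 0.75% of the image diagonal, unrounded."""
    h, w = shape
    return BOUNDARY_TOLERANCE_FRACTION * float(np.hypot(h, w))


def _bf_one_class(pred_b: np.ndarray, truth_b: np.ndarray, theta: float) -> float:
    np_pred, np_truth = int(pred_b.sum()), int(truth_b.sum())
    if np_pred == 0 and np_truth == 0:
        return 1.0                       # both boundaries empty: no error
    if np_pred == 0 or np_truth == 0:
        return 0.0
    d_truth = ndimage.distance_transform_edt(truth_b == 0)
    d_pred = ndimage.distance_transform_edt(pred_b == 0)
    precision = float(np.sum(d_truth[pred_b == 1] <= theta)) / np_pred
    recall = float(np.sum(d_pred[truth_b == 1] <= theta)) / np_truth
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def mbf(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean boundary F1 of the foreground and background classes."""
    pred = as_binary_mask(pred)
    truth = as_binary_mask(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    theta = boundary_tolerance(pred.shape)
    scores = []
    for cls_pred, cls_truth in ((pred, truth), (1 - pred, 1 - truth)):
        scores.append(_bf_one_class(boundary_pixels(cls_pred),
                                    boundary_pixels(cls_truth), theta))
    return float(np.mean(scores))


def ass(N: int, T: float) -> float:
    """Average segmentation speed in slices per second."""
    if N == 0:
        return 0.0
    if T <= 0:
        raise ValueError("elapsed time must be positive")
    return N / T
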