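"""Evaluation metrics: pixel confusion matrices, IoU / pixel accuracy for
segmentation, and precision-recall / average precision for detection.

Per-class pixel accuracy is implemented exactly as printed in the method this
package realizes — (TP + TN) / (TP + TN + FP + FN), i.e. including true
negatives — with the more common recall-style PA = TP / (TP + FN) available
via ``include_tn=False``. Classes absent from both prediction and ground
truth are excluded from the means (their ratios are 0/0).

Dataset-level evaluation pools a single global confusion matrix rather than
averaging per-image metrics; pooling is robust to images whose leaves cover
few pixels.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .detlosses import box_iou
from .formats import Box

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "iou_per_class",
    "miou",
    "pa_per_class",
    "mpa",
    "Detection",
    "PRCurve",
    "detection_pr",
    "ap",
    "average_precision",
    "mean_ap",
]


@dataclasses.dataclass
class ConfusionMatrix:
    """Pixel cross-tabulation; ``counts[g, p]`` = pixels of ground-truth class
    g predicted as class p. Additive across images."""

    counts: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def present(self) -> np.ndarray:
        """Classes that occur in ground truth or prediction."""
        return (self.counts.sum(axis=1) + self.counts.sum(axis=0)) > 0


def confusion(pred: np.ndarray, gt: np.ndarray, n_classes: int) -> ConfusionMatrix:
    """Exact pixel confusion matrix of a predicted vs ground-truth mask."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    if pred.max(initial=0) >= n_classes or gt.max(initial=0) >= n_classes:
        raise ValueError("mask values must be < n_classes")
    idx = gt.astype(np.int64).ravel() * n_classes + pred.astype(np.int64).ravel()
    counts = np.bincount(idx, minlength=n_classes * n_classes)
    return ConfusionMatrix(counts.reshape(n_classes, n_classes))


def iou_per_class(cm: ConfusionMatrix) -> np.ndarray:
    """Per-class TP / (TP + FP + FN); NaN where the class is absent entirely."""
    c = cm.counts.astype(np.float64)
    tp = np.diag(c)
    denom = c.sum(axis=1) + c.sum(axis=0) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, tp / denom, np.nan)


def miou(cm: ConfusionMatrix, include_background: bool = True) -> float:
    """Mean IoU over classes present in ground truth or prediction."""
    vals = iou_per_class(cm)
    if not include_background:
        vals = vals[1:]
    return float(np.nanmean(vals))


def pa_per_class(cm: ConfusionMatrix, include_tn: bool = True) -> np.ndarray:
    """Per-class pixel accuracy; NaN for classes absent from gt and pred.

    ``include_tn=True`` (default) is the printed form (TP + TN) / total;
    ``include_tn=False`` gives the recall-style TP / (TP + FN), undefined
    (NaN) when the class never occurs in ground truth.
    """
    c = cm.counts.astype(np.float64)
    tp = np.diag(c)
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        if include_tn:
            tn = cm.total - row - col + tp
            vals = (tp + tn) / cm.total if cm.total > 0 else np.full_like(tp, np.nan)
            return np.where((row + col) > 0, vals, np.nan)
        return np.where(row > 0, tp / row, np.nan)


def mpa(cm: ConfusionMatrix, include_tn: bool = True,
        include_background: bool = True) -> float:
    vals = pa_per_class(cm, include_tn=include_tn)
    if not include_background:
        vals = vals[1:]
    return float(np.nanmean(vals))


@dataclasses.dataclass(frozen=True)
class Detection:
    box: Box
    class_id: int
    confidence: float

    def __post_init__(self):
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence outside [0, 1]")


@dataclasses.dataclass
class PRCurve:
    """Precision/recall at each confidence-ranked detection prefix."""

    recall: np.ndarray
    precision: np.ndarray
    n_gt: int


def detection_pr(dets: Sequence[Detection], gts: Sequence[Box],
                 iou_thresh: float = 0.5) -> PRCurve:
    """Greedy matching in descending confidence; each ground-truth box is
    consumed by at most one detection, a match needs IoU >= iou_thresh."""
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    matched = [False] * len(gts)
    tp = np.zeros(len(dets))
    for rank, i in enumerate(order):
        best, best_iou = -1, iou_thresh
        for j, g in enumerate(gts):
            if matched[j]:
                continue
            v = box_iou(dets[i].box, g)
            if v >= best_iou:
                best, best_iou = j, v
        if best >= 0:
            matched[best] = True
            tp[rank] = 1.0
    cum_tp = np.cumsum(tp)
    ranks = np.arange(1, len(dets) + 1)
    recall = cum_tp / len(gts) if gts else np.zeros(len(dets))
    precision = cum_tp / ranks
    return PRCurve(recall, precision, len(gts))


def ap(curve: PRCurve) -> float:
    """Area under the PR curve with all-points interpolation (the precision
    envelope integrated over recall)."""
    if curve.n_gt == 0 or curve.recall.size == 0:
        return 0.0
    r = np.concatenate([[0.0], curve.recall, [curve.recall[-1]]])
    p = np.concatenate([[0.0], curve.precision, [0.0]])
    # running max from the right = interpolated precision
    for i in range(p.size - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    steps = np.flatnonzero(np.diff(r) > 0)
    return float(np.sum((r[steps + 1] - r[steps]) * p[steps + 1]))


def average_precision(dets: Sequence[Detection], gts: Sequence[Box],
                      iou_thresh: float = 0.5) -> float:
    return ap(detection_pr(dets, gts, iou_thresh))


def mean_ap(
    dets_by_class: dict[int, Sequence[Detection]],
    gts_by_class: dict[int, Sequence[Box]],
    iou_thresholds: Sequence[float] = (0.5,),
) -> float:
    """mAP over species, optionally averaged over an IoU-threshold grid
    (use ``np.arange(0.5, 1.0, 0.05)`` for the COCO-style mAP50-95)."""
    classes = sorted(set(gts_by_class) | set(dets_by_class))
    if not classes:
        return 0.0
    vals = []
    for c in classes:
        for t in iou_thresholds:
            vals.append(average_precision(
                dets_by_class.get(c, []), gts_by_class.get(c, []), t))
    return float(np.mean(vals))
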