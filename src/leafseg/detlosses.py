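"""Detection-stage losses and the task-aligned sample score.

These are the scalar building blocks of an anchor-free detection head:

* task-aligned score  t = s^mu * u^beta  (classification score s weighted with
  box IoU u) used to rank candidate positive samples;
* varifocal loss (VFL), an asymmetrically weighted binary cross-entropy whose
  positive targets are IoU values;
* complete-IoU (CIoU) loss for box regression, adding center-distance and
  aspect-ratio penalties to 1 - IoU;
* distribution focal loss (DFL), cross-entropy on the two discrete bin
  probabilities bracketing a continuous box-edge target.

All logarithms are natural; arguments are clamped at ``EPS`` before any log.
The hyperparameter defaults (mu=1, beta=6, omega=0.75, gamma=2) follow the
conventions of the task-aligned-assigner and varifocal-loss lineages; every
one is an explicit argument.
"""

from __future__ import annotations

import math

import numpy as np

from .formats import Box

__all__ = [
    "EPS",
    "box_iou",
    "alignment_score",
    "varifocal_loss",
    "ciou_loss",
    "dfl",
    "select_topk_by_alignment",
]

EPS = 1e-12


def _check01(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name}={value} outside [0, 1]")


def box_iou(a: Box, b: Box) -> float:
    """Intersection over union of two pixel boxes."""
    ix = max(0.0, min(a.x2, b.x2) - max(a.x1, b.x1))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y1, b.y1))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def alignment_score(s: float, u: float, mu: float = 1.0, beta: float = 6.0) -> float:
    """Task-aligned degree of a candidate: classification score s to the power
    mu times box IoU u to the power beta; lies in [0, 1]."""
    _check01(s, "s")
    _check01(u, "u")
    if mu < 0 or beta < 0:
        raise ValueError("mu and beta must be >= 0")
    return s**mu * u**beta


def varifocal_loss(p: float, q: float, omega: float = 0.75, gamma: float = 2.0) -> float:
    """Asymmetric IoU-aware classification loss.

    For positives (q > 0, q is the IoU label) the binary cross-entropy is
    scaled by q; for negatives (q = 0) the easy-sample term is down-weighted
    by omega * p**gamma. The 0*log(0) case is taken as 0.
    """
    _check01(p, "p")
    _check01(q, "q")
    log_p = math.log(max(p, EPS))
    log_1mp = math.log(max(1.0 - p, EPS))
    if q > 0:
        term = q * log_p if q > 0 else 0.0
        term += (1.0 - q) * log_1mp if q < 1.0 else 0.0
        return -q * term
    return -omega * p**gamma * log_1mp


def ciou_loss(pred: Box, gt: Box) -> float:
    """Complete-IoU loss: 1 - IoU + normalized center distance + aspect penalty.

    The aspect term is v = (4/pi^2) * (arctan(w_gt/h_gt) - arctan(w_p/h_p))^2
    with trade-off alpha = v / ((1 - IoU) + v); the distance term divides the
    squared center distance by the squared diagonal of the smallest box
    enclosing both.
    """
    iou = box_iou(pred, gt)
    (pcx, pcy), (gcx, gcy) = pred.center, gt.center
    rho2 = (pcx - gcx) ** 2 + (pcy - gcy) ** 2
    cw = max(pred.x2, gt.x2) - min(pred.x1, gt.x1)
    ch = max(pred.y2, gt.y2) - min(pred.y1, gt.y1)
    c2 = cw**2 + ch**2
    v = (4.0 / math.pi**2) * (math.atan(gt.w / gt.h) - math.atan(pred.w / pred.h)) ** 2
    alpha = v / ((1.0 - iou) + v) if v > 0 else 0.0
    return 1.0 - iou + rho2 / c2 + alpha * v


def dfl(y: float, y_i: float, s_i: float, s_ip1: float) -> float:
    """Distribution focal loss for a continuous target y bracketed by the
    integer grid points y_i and y_i + 1 with predicted probabilities s_i,
    s_{i+1}: -((y_{i+1} - y) log s_i + (y - y_i) log s_{i+1})."""
    y_ip1 = y_i + 1.0
    if not (y_i <= y <= y_ip1):
        raise ValueError(f"target y={y} outside [{y_i}, {y_ip1}]")
    for name, s in (("s_i", s_i), ("s_ip1", s_ip1)):
        if not (0.0 < s <= 1.0):
            raise ValueError(f"{name}={s} outside (0, 1]")
    wl, wr = y_ip1 - y, y - y_i
    loss = 0.0
    if wl > 0:
        loss -= wl * math.log(max(s_i, EPS))
    if wr > 0:
        loss -= wr * math.log(max(s_ip1, EPS))
    return loss


def select_topk_by_alignment(
    scores: np.ndarray, ious: np.ndarray, k: int,
    mu: float = 1.0, beta: float = 6.0,
) -> np.ndarray:
    """Indices of the k candidates with the largest task-aligned score,
    in descending score order (the positive-sample pre-selection step)."""
    scores = np.asarray(scores, dtype=np.float64)
    ious = np.asarray(ious, dtype=np.float64)
    if scores.shape != ious.shape:
        raise ValueError("scores and ious must have the same shape")
    t = scores**mu * ious**beta
    order = np.argsort(-t, kind="stable")
    return order[: min(k, t.size)]
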