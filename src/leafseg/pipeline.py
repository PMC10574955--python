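"""Two-stage inference and the segmentation training loop.

Stage one is any detector honouring ``DetectorInterface`` (an external
detector's YOLO txt output, or the ground-truth boxes); stage two crops each
detection with a small padding margin, letterbox-resizes the crop to the
model input, segments it, and pastes the predicted mask back into the full
frame. Cropping first is what removes background interference from the
segmentation stage.

Training optimizes mean pixelwise cross-entropy with SGD (momentum + L2
weight decay) under a polynomial learning-rate decay of power 0.9. With
``crops=True`` the model is trained on ground-truth-box crops — the regime
the two-stage pipeline sees at inference time.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from PIL import Image

from . import nn
from .formats import (
    Box,
    DatasetManifest,
    read_mask,
    read_yolo_labels,
    yolo_to_box,
)
from .segnet import SegModel, SegModelConfig, build_model
from .synthleaf import tight_box

__all__ = [
    "DetectorInterface",
    "YoloTxtDetector",
    "GroundTruthDetector",
    "TrainConfig",
    "crop_with_padding",
    "paste_back",
    "letterbox",
    "unletterbox",
    "segment_image",
    "run_two_stage",
    "train_segmentation",
    "evaluate_model",
]

#: detector contract: RGB image -> [(box, class_id, confidence), ...]
DetectorInterface = Callable[[np.ndarray], list[tuple[Box, int, float]]]


class YoloTxtDetector:
    """Detector backed by pre-computed YOLO txt files (one per image stem),
    letting any external detector slot into the pipeline."""

    def __init__(self, label_dir: str | Path, confidence: float = 1.0):
        self.label_dir = Path(label_dir)
        self.confidence = confidence
        self._current_stem: str | None = None

    def for_stem(self, stem: str) -> "YoloTxtDetector":
        self._current_stem = stem
        return self

    def __call__(self, image: np.ndarray) -> list[tuple[Box, int, float]]:
        if self._current_stem is None:
            raise RuntimeError("call for_stem() before detecting")
        h, w = image.shape[:2]
        labels = read_yolo_labels(self.label_dir / f"{self._current_stem}.txt")
        return [(yolo_to_box(l, w, h), l.class_id, self.confidence) for l in labels]


class GroundTruthDetector:
    """Oracle detector returning the tight box of a ground-truth mask."""

    def __init__(self, mask: np.ndarray):
        self.mask = mask

    def __call__(self, image: np.ndarray) -> list[tuple[Box, int, float]]:
        if not self.mask.any():
            return []
        cls = int(self.mask.max()) - 1
        return [(tight_box(self.mask), cls, 1.0)]


@dataclasses.dataclass
class TrainConfig:
    """Segmentation training hyperparameters (defaults are the reference
    schedule: 200 epochs, batch 8, lr 0.01, momentum 0.9, weight decay 1e-4)."""

    epochs: int = 200
    batch_size: int = 8
    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4
    seed: int = 0
    lr_power: float = 0.9  # polynomial decay exponent

    def __post_init__(self):
        for name in ("epochs", "batch_size", "lr", "momentum", "weight_decay"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# crop / paste geometry


def crop_with_padding(
    image: np.ndarray,
    mask: np.ndarray | None,
    box: Box,
    pad_frac: float = 0.1,
) -> tuple[np.ndarray, np.ndarray | None, Box]:
    """Crop ``box`` expanded by ``pad_frac`` per side, clamped to the frame.

    Returns the crop, the equally cropped mask (or None), and the integer
    placement rectangle used by :func:`paste_back`.
    """
    h, w = image.shape[:2]
    px, py = box.w * pad_frac, box.h * pad_frac
    x1 = int(np.floor(max(box.x1 - px, 0)))
    y1 = int(np.floor(max(box.y1 - py, 0)))
    x2 = int(np.ceil(min(box.x2 + px, w)))
    y2 = int(np.ceil(min(box.y2 + py, h)))
    if x2 <= x1 or y2 <= y1:
        raise ValueError("box does not intersect the image")
    placement = Box(float(x1), float(y1), float(x2), float(y2))
    crop = image[y1:y2, x1:x2].copy()
    crop_mask = mask[y1:y2, x1:x2].copy() if mask is not None else None
    return crop, crop_mask, placement


def paste_back(full_shape: tuple[int, int], crop_mask: np.ndarray,
               placement: Box, out: np.ndarray | None = None) -> np.ndarray:
    """Place a crop-sized mask into a full-size frame (background elsewhere).

    Passing ``out`` accumulates several placements; later calls overwrite
    earlier ones inside their rectangle, so callers order detections by
    ascending confidence to give the most confident detection the last word.
    """
    x1, y1, x2, y2 = placement.as_int()
    if x1 < 0 or y1 < 0 or x2 > full_shape[1] or y2 > full_shape[0]:
        raise ValueError("placement outside the full frame")
    if crop_mask.shape != (y2 - y1, x2 - x1):
        raise ValueError(f"crop mask {crop_mask.shape} does not match "
                         f"placement {(y2 - y1, x2 - x1)}")
    if out is None:
        out = np.zeros(full_shape, dtype=crop_mask.dtype)
    out[y1:y2, x1:x2] = crop_mask
    return out


# ---------------------------------------------------------------------------
# letterboxing


def letterbox(image: np.ndarray, size: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Aspect-preserving resize onto a size x size canvas (top-left anchored).

    Returns the canvas and the (h', w') of the valid region. Slender shapes
    keep their aspect ratio instead of being stretched square.
    """
    h, w = image.shape[:2]
    scale = size / max(h, w)
    nh, nw = max(1, round(h * scale)), max(1, round(w * scale))
    pil = Image.fromarray(image)
    interp = Image.NEAREST if image.ndim == 2 else Image.BILINEAR
    resized = np.asarray(pil.resize((nw, nh), interp))
    canvas_shape = (size, size) + image.shape[2:]
    canvas = np.zeros(canvas_shape, dtype=image.dtype)
    canvas[:nh, :nw] = resized
    return canvas, (nh, nw)


def unletterbox(mask: np.ndarray, orig_hw: tuple[int, int],
                valid_hw: tuple[int, int]) -> np.ndarray:
    """Invert :func:`letterbox` for a predicted class mask (nearest resize)."""
    nh, nw = valid_hw
    pil = Image.fromarray(mask[:nh, :nw])
    return np.asarray(pil.resize((orig_hw[1], orig_hw[0]), Image.NEAREST))


def _normalize(image: np.ndarray) -> np.ndarray:
    """HWC uint8 -> CHW float32 in [-1, 1]."""
    x = image.astype(np.float32) / 255.0
    return np.moveaxis((x - 0.5) / 0.5, -1, 0)


def segment_image(model: SegModel, image: np.ndarray) -> np.ndarray:
    """Segment one RGB image (any size) into a class mask of the same size."""
    size = model.cfg.input_size
    canvas, valid = letterbox(image, size)
    model.eval()
    logits = model(nn.Tensor(_normalize(canvas)[None]))
    pred = np.argmax(logits.data[0], axis=0).astype(np.uint8)
    return unletterbox(pred, image.shape[:2], valid)


def run_two_stage(
    image: np.ndarray,
    detector: DetectorInterface,
    model: SegModel,
    pad_frac: float = 0.1,
) -> np.ndarray:
    """Detect, crop, segment, paste back. No detections -> all background.

    Detections are processed in ascending confidence so that in overlaps the
    most confident detection's pixels win.
    """
    full = np.zeros(image.shape[:2], dtype=np.uint8)
    detections = sorted(detector(image), key=lambda d: d[2])
    for box, _cls, _conf in detections:
        crop, _, placement = crop_with_padding(image, None, box, pad_frac)
        crop_mask = segment_image(model, crop)
        paste_back(image.shape[:2], crop_mask, placement, out=full)
    return full


# ---------------------------------------------------------------------------
# training


def _load_pair(record, input_size: int, crops: bool, pad_frac: float):
    image = np.asarray(Image.open(record.image_path).convert("RGB"))
    mask = read_mask(record.mask_path)
    if crops:
        labels = read_yolo_labels(record.label_path)
        if labels:
            box = yolo_to_box(labels[0], image.shape[1], image.shape[0])
        else:
            box = tight_box(mask)
        image, mask, _ = crop_with_padding(image, mask, box, pad_frac)
    img_c, valid = letterbox(image, input_size)
    mask_c, _ = letterbox(mask, input_size)
    return _normalize(img_c), mask_c.astype(np.int64)


def load_split_arrays(
    manifest: DatasetManifest, split: str, input_size: int,
    crops: bool = False, pad_frac: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack one split into (N, 3, S, S) inputs and (N, S, S) targets."""
    records = manifest.by_split(split)
    if not records:
        raise ValueError(f"split '{split}' is empty")
    pairs = [_load_pair(r, input_size, crops, pad_frac) for r in records]
    return (np.stack([p[0] for p in pairs]),
            np.stack([p[1] for p in pairs]))


def train_segmentation(
    manifest: DatasetManifest,
    model_cfg: SegModelConfig,
    train_cfg: TrainConfig,
    crops: bool = False,
    pad_frac: float = 0.1,
    loss_csv: str | Path | None = None,
) -> tuple[SegModel, list[float]]:
    """Train on the manifest's train split; returns the model and the
    per-epoch mean loss trace. Fully seeded and single-threaded, so the same
    configuration reproduces the same trace bit for bit."""
    x, y = load_split_arrays(manifest, "train", model_cfg.input_size, crops, pad_frac)
    model = build_model(model_cfg, seed=train_cfg.seed)
    model.train()
    opt = nn.SGD(model.parameters(), train_cfg.lr, train_cfg.momentum,
                 train_cfg.weight_decay)
    rng = np.random.default_rng(train_cfg.seed)
    n = x.shape[0]
    steps_per_epoch = max(1, int(np.ceil(n / train_cfg.batch_size)))
    total_steps = train_cfg.epochs * steps_per_epoch
    losses: list[float] = []
    step = 0
    for _epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for b in range(steps_per_epoch):
            idx = order[b * train_cfg.batch_size : (b + 1) * train_cfg.batch_size]
            opt.lr = train_cfg.lr * (1.0 - step / total_steps) ** train_cfg.lr_power
            model.zero_grad()
            logits = model(nn.Tensor(x[idx]))
            loss = nn.cross_entropy(logits, y[idx])
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
            step += 1
        losses.append(float(np.mean(epoch_losses)))
    if loss_csv is not None:
        with open(loss_csv, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "loss"])
            for i, l in enumerate(losses):
                writer.writerow([i, f"{l:.6f}"])
    return model, losses


def evaluate_model(
    model: SegModel,
    images: Sequence[np.ndarray],
    gt_masks: Sequence[np.ndarray],
    n_classes: int,
    detectors: Sequence[DetectorInterface] | None = None,
    pad_frac: float = 0.1,
) -> dict:
    """Pooled-confusion mIoU/mPA of the model over a set of images.

    With ``detectors`` given (one per image) the two-stage path is used;
    otherwise each full image is segmented directly.
    """
    from .metrics import ConfusionMatrix, confusion, miou, mpa

    cm = ConfusionMatrix(np.zeros((n_classes, n_classes), dtype=np.int64))
    for i, (img, gt) in enumerate(zip(images, gt_masks)):
        if detectors is not None:
            pred = run_two_stage(img, detectors[i], model, pad_frac)
        else:
            pred = segment_image(model, img)
        cm = cm + confusion(pred, gt, n_classes)
    return {"miou": miou(cm), "mpa": mpa(cm), "confusion": cm}
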