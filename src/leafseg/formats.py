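"""Dataset on-disk formats: YOLO txt detection labels, VOC-style palette PNG
masks, and train/val/test split bookkeeping.

Conventions
-----------
* Pixel coordinates have their origin at the top-left corner; boxes are
  half-open ``[x1, x2) x [y1, y2)`` so that cropping is off-by-one free.
* YOLO label lines are ``class cx cy w h`` with center/size normalized to the
  unit square.
* Segmentation masks are 8-bit palette-indexed PNGs where index 0 is
  background and indices ``1..N`` are leaf species.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from PIL import Image

__all__ = [
    "DetectionLabel",
    "Box",
    "ImageRecord",
    "DatasetManifest",
    "LabelParseError",
    "read_yolo_labels",
    "write_yolo_labels",
    "yolo_to_box",
    "box_to_yolo",
    "make_palette",
    "read_mask",
    "write_mask",
    "split_dataset",
    "write_manifest",
    "read_manifest",
]

SPLITS = ("train", "val", "test")

#: values this far outside [0, 1] are clamped rather than rejected
#: (annotation tools emit boundary jitter)
CLAMP_TOL = 1e-3


class LabelParseError(ValueError):
    """Raised for malformed YOLO label files; message names the line."""


@dataclasses.dataclass(frozen=True)
class DetectionLabel:
    """One normalized YOLO detection: class id plus box center/size in [0, 1]."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if self.class_id < 0:
            raise ValueError(f"class_id must be >= 0, got {self.class_id}")
        for name in ("cx", "cy", "w", "h"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.w == 0 or self.h == 0:
            raise ValueError("degenerate zero-size box")


@dataclasses.dataclass(frozen=True)
class Box:
    """Axis-aligned pixel box, half-open, origin top-left; requires x1<x2, y1<y2."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self):
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValueError(f"degenerate box {self}")

    @property
    def w(self) -> float:
        return self.x2 - self.x1

    @property
    def h(self) -> float:
        return self.y2 - self.y1

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x1 + self.x2), 0.5 * (self.y1 + self.y2))

    @property
    def area(self) -> float:
        return self.w * self.h

    def as_int(self) -> tuple[int, int, int, int]:
        """Integer pixel bounds, rounding outward never past the original box."""
        return (int(round(self.x1)), int(round(self.y1)),
                int(round(self.x2)), int(round(self.y2)))


@dataclasses.dataclass
class ImageRecord:
    image_path: str
    species_id: int
    split: str = "train"
    label_path: str = ""
    mask_path: str = ""

    def __post_init__(self):
        if self.species_id < 1:
            raise ValueError("species_id starts at 1 (0 is background)")
        if self.split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}")

    @property
    def stem(self) -> str:
        return Path(self.image_path).stem


@dataclasses.dataclass
class DatasetManifest:
    records: list[ImageRecord]
    n_species: int

    def by_split(self, split: str) -> list[ImageRecord]:
        return [r for r in self.records if r.split == split]

    def counts(self) -> dict[str, int]:
        return {s: len(self.by_split(s)) for s in SPLITS}


def _clamp01(v: float, what: str, lineno: int) -> float:
    if -CLAMP_TOL <= v < 0.0:
        return 0.0
    if 1.0 < v <= 1.0 + CLAMP_TOL:
        return 1.0
    if 0.0 <= v <= 1.0:
        return v
    raise LabelParseError(f"line {lineno}: {what}={v} outside [0, 1]")


def read_yolo_labels(path: str | Path) -> list[DetectionLabel]:
    """Parse a YOLO txt label file (one ``class cx cy w h`` line per object)."""
    labels = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 5:
                raise LabelParseError(
                    f"line {lineno}: expected 5 fields, got {len(fields)}")
            try:
                cls = int(fields[0])
                vals = [float(f) for f in fields[1:]]
            except ValueError as exc:
                raise LabelParseError(f"line {lineno}: {exc}") from exc
            cx, cy, w, h = (
                _clamp01(v, name, lineno)
                for v, name in zip(vals, ("cx", "cy", "w", "h"))
            )
            try:
                labels.append(DetectionLabel(cls, cx, cy, w, h))
            except ValueError as exc:
                raise LabelParseError(f"line {lineno}: {exc}") from exc
    return labels


def write_yolo_labels(labels: Iterable[DetectionLabel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for lab in labels:
            fh.write(f"{lab.class_id} {lab.cx:.6f} {lab.cy:.6f} "
                     f"{lab.w:.6f} {lab.h:.6f}\n")


def yolo_to_box(label: DetectionLabel, img_w: int, img_h: int) -> Box:
    """Convert a normalized label to a pixel box, clamped to the image."""
    if img_w <= 0 or img_h <= 0:
        raise ValueError("image dimensions must be positive")
    x1 = max((label.cx - label.w / 2) * img_w, 0.0)
    y1 = max((label.cy - label.h / 2) * img_h, 0.0)
    x2 = min((label.cx + label.w / 2) * img_w, float(img_w))
    y2 = min((label.cy + label.h / 2) * img_h, float(img_h))
    if not (x1 < x2 and y1 < y2):
        raise ValueError("box has zero area after clamping to the image")
    return Box(x1, y1, x2, y2)


def box_to_yolo(box: Box, img_w: int, img_h: int, class_id: int = 0) -> DetectionLabel:
    cx, cy = box.center
    return DetectionLabel(class_id, cx / img_w, cy / img_h,
                          box.w / img_w, box.h / img_h)


def make_palette(n_classes: int, seed: int = 0) -> np.ndarray:
    """Deterministic (n_classes, 3) uint8 palette; index 0 is black background."""
    rng = np.random.default_rng(seed)
    pal = rng.integers(32, 256, size=(n_classes, 3), dtype=np.int64).astype(np.uint8)
    pal[0] = 0
    return pal


def write_mask(mask: np.ndarray, path: str | Path, palette: np.ndarray | None = None) -> None:
    """Write a 2-D class-index mask as an 8-bit palette PNG."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if mask.min() < 0 or mask.max() > 255:
        raise ValueError("mask values must fit uint8 palette indices")
    if palette is None:
        palette = make_palette(int(mask.max()) + 1)
    img = Image.fromarray(mask.astype(np.uint8), mode="P")
    flat = np.zeros(768, dtype=np.uint8)
    flat[: palette.size] = palette.ravel()
    img.putpalette(flat.tolist())
    img.save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a palette PNG as a 2-D array of class indices."""
    img = Image.open(path)
    if img.mode != "P":
        raise ValueError(
            f"{path}: expected a palette-indexed PNG (mode 'P'), got mode "
            f"'{img.mode}'; convert the mask to palette form first")
    return np.asarray(img, dtype=np.uint8)


def _apportion(sizes: Sequence[int], total: int) -> list[int]:
    """Largest-remainder apportionment of ``total`` across groups of ``sizes``."""
    n = sum(sizes)
    quotas = [s * total / n for s in sizes]
    base = [int(q) for q in quotas]
    short = total - sum(base)
    order = sorted(range(len(sizes)), key=lambda i: (base[i] - quotas[i], i))
    for i in order[:short]:
        base[i] += 1
    return base


def split_dataset(
    records: Sequence[ImageRecord],
    val_count: int,
    test_count: int,
    seed: int,
    n_species: int | None = None,
) -> DatasetManifest:
    """Assign train/val/test splits, stratified by species.

    Each species contributes to val/test in proportion to its size
    (largest-remainder rounding); leftovers stay in train. The within-species
    assignment is a seeded permutation, so the same seed reproduces the same
    manifest exactly.
    """
    records = list(records)
    if val_count + test_count >= len(records):
        raise ValueError("val_count + test_count must be < number of records")
    species = sorted({r.species_id for r in records})
    if n_species is None:
        n_species = max(species)
    groups = {s: [i for i, r in enumerate(records) if r.species_id == s] for s in species}
    sizes = [len(groups[s]) for s in species]
    val_q = _apportion(sizes, val_count)
    test_q = _apportion(sizes, test_count)
    rng = np.random.default_rng(seed)
    out = [dataclasses.replace(r, split="train") for r in records]
    for s, nv, nt in zip(species, val_q, test_q):
        idx = np.array(groups[s])
        rng.shuffle(idx)
        if nv + nt > len(idx):
            raise ValueError(f"species {s}: quota exceeds group size")
        for i in idx[:nv]:
            out[i].split = "val"
        for i in idx[nv : nv + nt]:
            out[i].split = "test"
    return DatasetManifest(out, n_species)


def write_manifest(manifest: DatasetManifest, out_dir: str | Path) -> None:
    """VOC ImageSets-style split lists plus a YAML config naming roots."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for split in SPLITS:
        with open(out_dir / f"{split}.txt", "w") as fh:
            for r in manifest.by_split(split):
                fh.write(r.stem + "\n")

    def _rel(p: str) -> str:
        # paths under the manifest root are stored relative, keeping the
        # written tree byte-identical across runs in different directories
        try:
            return str(Path(p).resolve().relative_to(out_dir.resolve()))
        except ValueError:
            return p

    meta = {
        "n_species": manifest.n_species,
        "records": [
            {**dataclasses.asdict(r),
             **{k: _rel(getattr(r, k))
                for k in ("image_path", "label_path", "mask_path")
                if getattr(r, k)}}
            for r in manifest.records
        ],
    }
    with open(out_dir / "dataset.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_manifest(path: str | Path) -> DatasetManifest:
    path = Path(path)
    if path.is_dir():
        path = path / "dataset.yaml"
    with open(path) as fh:
        meta = yaml.safe_load(fh)
    root = path.parent

    def _abs(p: str) -> str:
        return p if (not p or Path(p).is_absolute()) else str(root / p)

    records = []
    for r in meta["records"]:
        for k in ("image_path", "label_path", "mask_path"):
            r[k] = _abs(r.get(k, ""))
        records.append(ImageRecord(**r))
    return DatasetManifest(records, int(meta["n_species"]))
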