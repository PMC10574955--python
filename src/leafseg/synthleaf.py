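"""Seeded synthetic single-leaf images with paired masks and tight boxes.

The generator emulates the photograph types the segmentation method targets:
one dominant leaf blade (rounded, lobed, or bar/strip shaped) with a slender
petiole, optional dark spots and withering discoloration, over a cluttered
non-leaf background. It exists so that detection-box cropping, the
segmentation head, and the metrics can all be exercised end-to-end without any
real dataset — the shapes are procedural, and realism is explicitly not the
goal; mechanism correctness is.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter, zoom
from skimage.draw import disk, polygon

from .formats import (
    Box,
    DatasetManifest,
    ImageRecord,
    box_to_yolo,
    make_palette,
    split_dataset,
    write_manifest,
    write_mask,
    write_yolo_labels,
)

__all__ = ["LeafSpec", "SyntheticSample", "generate_sample", "generate_dataset",
           "tight_box", "BROWN_RGB", "GREEN_HUE_BAND", "species_base_color"]

BLADE_KINDS = ("ellipse", "lobed", "bar")

#: fully-withered tissue color; wither_level interpolates the species base
#: color (see species_base_color) toward it
BROWN_RGB = np.array([128, 96, 48], dtype=np.float32)

#: hue band (HSV hue in [0, 1]) that un-withered foreground stays inside
GREEN_HUE_BAND = (0.18, 0.45)

_GOLDEN = 0.6180339887498949


def species_base_color(species_id: int) -> np.ndarray:
    """Deterministic healthy-tissue color of a species, inside the green band.

    Species are told apart by foliage tone (hue/saturation/value jittered on a
    low-discrepancy sequence), the cue the segmentation stage must learn to
    classify them — same-shaped leaves of different species look different.
    """
    import colorsys

    h = 0.22 + 0.16 * ((species_id * _GOLDEN) % 1.0)
    s = 0.55 + 0.25 * ((species_id * _GOLDEN * 7) % 1.0)
    v = 0.40 + 0.22 * ((species_id * _GOLDEN * 13) % 1.0)
    return np.array(colorsys.hsv_to_rgb(h, s, v), dtype=np.float32) * 255.0


@dataclasses.dataclass(frozen=True)
class LeafSpec:
    """Parameters of one synthetic leaf photograph."""

    species_id: int
    blade_kind: str = "ellipse"
    petiole_length_frac: float = 0.2
    petiole_width_px: int = 2
    spot_density: float = 0.0
    wither_level: float = 0.0
    background_clutter: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.species_id < 1:
            raise ValueError("species_id starts at 1")
        if self.blade_kind not in BLADE_KINDS:
            raise ValueError(f"blade_kind must be one of {BLADE_KINDS}")
        if not (0.0 <= self.petiole_length_frac <= 0.5):
            raise ValueError("petiole_length_frac outside [0, 0.5]")
        if self.petiole_width_px < 1:
            raise ValueError("petiole_width_px must be >= 1")
        if self.spot_density < 0:
            raise ValueError("spot_density must be >= 0")
        if not (0.0 <= self.wither_level <= 1.0):
            raise ValueError("wither_level outside [0, 1]")
        if not (0.0 <= self.background_clutter <= 1.0):
            raise ValueError("background_clutter outside [0, 1]")


@dataclasses.dataclass
class SyntheticSample:
    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray   # (H, W) uint8, 0 = background, species_id = leaf
    box: Box           # tight bounding box of the mask foreground
    spec: LeafSpec


def tight_box(mask: np.ndarray) -> Box:
    """Tight half-open bounding box of a mask's nonzero region."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("mask has no foreground")
    return Box(float(cols[0]), float(rows[0]), float(cols[-1] + 1), float(rows[-1] + 1))


def _blade_mask(spec: LeafSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    """Rasterize the blade as a closed polygon on a (size, size) grid."""
    theta = np.linspace(0.0, 2 * np.pi, 180, endpoint=False)
    if spec.blade_kind == "bar":
        # elongated strip, aspect ratio >= 6, slightly rotated
        half_len = size * (0.26 + 0.06 * rng.random())
        half_wid = half_len / (6.0 + 4.0 * rng.random())
        angle = rng.uniform(-0.35, 0.35)
        cx, cy = size * 0.5, size * 0.42
        corners = np.array(
            [[-half_wid, -half_len], [half_wid, -half_len],
             [half_wid, half_len], [-half_wid, half_len]])
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        pts = corners @ rot.T + [cx, cy]
        cc, rr = pts[:, 0], pts[:, 1]
    else:
        rx = size * (0.16 + 0.08 * rng.random())
        ry = rx * (1.15 + 0.45 * rng.random())
        cx, cy = size * (0.5 + rng.uniform(-0.05, 0.05)), size * 0.40
        r = np.ones_like(theta)
        # seeded radial perturbation keeps the outline smooth but irregular
        for k in (2, 3, 5):
            r += 0.05 * rng.standard_normal() * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
        if spec.blade_kind == "lobed":
            n_lobes = int(rng.integers(4, 7))
            r += 0.16 * np.abs(np.sin(n_lobes * theta / 2.0))
        r = np.clip(r, 0.55, 1.45)
        cc = cx + rx * r * np.cos(theta)
        rr = cy + ry * r * np.sin(theta)
    mask = np.zeros((size, size), dtype=bool)
    rr_i, cc_i = polygon(np.clip(rr, 0, size - 1), np.clip(cc, 0, size - 1), mask.shape)
    mask[rr_i, cc_i] = True
    return mask


def _attach_petiole(mask: np.ndarray, spec: LeafSpec, size: int) -> np.ndarray:
    """Draw a thin vertical strip hanging from the lowest blade pixel."""
    length = int(round(spec.petiole_length_frac * size))
    if length == 0:
        return mask
    rows = np.flatnonzero(mask.any(axis=1))
    bottom = rows[-1]
    cols = np.flatnonzero(mask[bottom])
    c0 = int(cols.mean())
    half = spec.petiole_width_px
    x_lo = max(c0 - (half - 1) // 2, 0)
    x_hi = min(x_lo + spec.petiole_width_px, size)
    y_hi = min(bottom + 1 + length, size)
    mask[bottom + 1 : y_hi, x_lo:x_hi] = True
    return mask


def _background(spec: LeafSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    base = np.array([105, 100, 92], dtype=np.float32)
    img = np.tile(base, (size, size, 1))
    if spec.background_clutter > 0:
        low = rng.normal(0.0, 55.0 * spec.background_clutter, size=(size // 8 + 1, size // 8 + 1, 3))
        factor = size / low.shape[0]
        noise = zoom(low, (factor, factor, 1), order=1)[:size, :size]
        img += gaussian_filter(noise, sigma=(1.5, 1.5, 0))
    return img


def _add_distractors(img: np.ndarray, leaf: np.ndarray, spec: LeafSpec,
                     rng: np.random.Generator) -> None:
    """Non-leaf-colored ellipses; any that would cover >= 30% of the leaf is skipped."""
    size = img.shape[0]
    n = int(round(6 * spec.background_clutter))
    leaf_area = max(int(leaf.sum()), 1)
    for _ in range(n):
        r0, c0 = rng.integers(0, size, size=2)
        rad = int(rng.integers(size // 16 + 1, size // 5 + 2))
        rr, cc = disk((r0, c0), rad, shape=img.shape[:2])
        blob = np.zeros_like(leaf)
        blob[rr, cc] = True
        if (blob & leaf).sum() >= 0.3 * leaf_area:
            continue
        hue_pool = [(70, 80, 160), (150, 60, 50), (120, 110, 130), (170, 140, 60)]
        color = np.array(hue_pool[int(rng.integers(len(hue_pool)))], dtype=np.float32)
        color += rng.normal(0, 12, size=3).astype(np.float32)
        img[rr, cc] = 0.7 * color + 0.3 * img[rr, cc]


def _paint_foreground(img: np.ndarray, mask: np.ndarray, spec: LeafSpec,
                      rng: np.random.Generator) -> None:
    green = species_base_color(spec.species_id)
    base = (1.0 - spec.wither_level) * green + spec.wither_level * BROWN_RGB
    fg = np.where(mask)
    texture = rng.normal(1.0, 0.06, size=(fg[0].size, 1)).astype(np.float32)
    img[fg] = base[None, :] * texture
    # dark circular lesions at spot_density per 1000 foreground px^2
    n_spots = int(round(spec.spot_density * fg[0].size / 1000.0))
    for _ in range(n_spots):
        k = int(rng.integers(fg[0].size))
        rad = int(rng.integers(1, 4))
        rr, cc = disk((fg[0][k], fg[1][k]), rad, shape=mask.shape)
        keep = mask[rr, cc]
        img[rr[keep], cc[keep]] = np.array([70, 55, 30], dtype=np.float32) * float(
            rng.uniform(0.8, 1.1))


def generate_sample(spec: LeafSpec, img_size: int = 64) -> SyntheticSample:
    """Render one synthetic leaf photograph with its mask and tight box."""
    if img_size < 32:
        raise ValueError("img_size must be >= 32")
    rng = np.random.default_rng(spec.seed)
    mask_bool = _blade_mask(spec, img_size, rng)
    mask_bool = _attach_petiole(mask_bool, spec, img_size)
    frac = mask_bool.mean()
    if not (0.02 <= frac <= 0.9):
        raise RuntimeError(f"foreground fraction {frac:.3f} outside [0.02, 0.9]")
    img = _background(spec, img_size, rng)
    _add_distractors(img, mask_bool, spec, rng)
    _paint_foreground(img, mask_bool, spec, rng)
    image = np.clip(img, 0, 255).astype(np.uint8)
    mask = mask_bool.astype(np.uint8) * spec.species_id
    return SyntheticSample(image, mask, tight_box(mask), spec)


def random_spec(species_id: int, seed: int, rng: np.random.Generator) -> LeafSpec:
    """Draw one leaf specification covering the blade/petiole/texture states."""
    return LeafSpec(
        species_id=species_id,
        blade_kind=BLADE_KINDS[int(rng.integers(len(BLADE_KINDS)))],
        petiole_length_frac=float(rng.uniform(0.1, 0.35)),
        petiole_width_px=int(rng.integers(1, 4)),
        spot_density=float(rng.choice([0.0, 0.0, 2.0, 6.0])),
        wither_level=float(rng.choice([0.0, 0.0, 0.3, 0.7])),
        background_clutter=float(rng.uniform(0.3, 0.9)),
        seed=seed,
    )


def generate_dataset(
    n: int,
    n_species: int,
    img_size: int,
    seed: int,
    out_dir: str | Path,
) -> DatasetManifest:
    """Write ``n`` image/mask/label triplets and an 8:1:1 split manifest.

    Layout: ``images/*.png``, ``masks/*.png`` (palette), ``labels/*.txt``
    (YOLO), plus VOC-style split lists and ``dataset.yaml`` at the root.
    """
    if n < n_species:
        raise ValueError("need at least one image per species")
    out_dir = Path(out_dir)
    for sub in ("images", "masks", "labels"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    palette = make_palette(n_species + 1)
    records = []
    for i in range(n):
        species = 1 + i % n_species
        spec = random_spec(species, int(master.integers(2**31)), master)
        sample = generate_sample(spec, img_size)
        stem = f"leaf_{i:05d}"
        img_path = out_dir / "images" / f"{stem}.png"
        mask_path = out_dir / "masks" / f"{stem}.png"
        label_path = out_dir / "labels" / f"{stem}.txt"
        Image.fromarray(sample.image).save(img_path)
        write_mask(sample.mask, mask_path, palette)
        # YOLO class ids are 0-based: species_id - 1
        write_yolo_labels(
            [box_to_yolo(sample.box, img_size, img_size, species - 1)], label_path)
        records.append(ImageRecord(str(img_path), species, "train",
                                   str(label_path), str(mask_path)))
    holdout = max(1, n // 10)
    manifest = split_dataset(records, holdout, holdout,
                             seed=int(master.integers(2**31)), n_species=n_species)
    write_manifest(manifest, out_dir)
    return manifest
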