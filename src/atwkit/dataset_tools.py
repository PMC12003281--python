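"""Dataset construction utilities: YOLO-format label I/O, the 8:1:1
train/val/test split, and the augmentation operators used to enrich a
seedling image set (affine, color distortion, Gaussian noise, Cutout,
Mosaic) plus environmental-condition presets (sun, dusk, fog, sensor
noise).

All operators act on :class:`LabeledImage` (an ``(H, W, 3)`` uint8 raster
plus YOLO-normalized boxes), are pure functions of their arguments, and are
bit-reproducible given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import color as _skcolor
from skimage import transform as _sktransform

from .detection_eval import Box, Detection

__all__ = [
    "LabeledImage",
    "DatasetManifest",
    "AffineSpec",
    "read_yolo_labels",
    "write_yolo_labels",
    "read_predictions",
    "write_predictions",
    "split_dataset",
    "affine",
    "color_distort",
    "gaussian_noise",
    "cutout",
    "mosaic",
    "environment_preset",
    "ENVIRONMENT_PRESETS",
]


@dataclass
class LabeledImage:
    """An RGB raster with its (normalized, center-format) boxes."""

    image: np.ndarray
    boxes: list[Box]

    def __post_init__(self):
        self.image = np.asarray(self.image)
        if self.image.ndim != 3 or self.image.shape[-1] != 3:
            raise ValueError(f"expected (H, W, 3) image, got {self.image.shape}")


@dataclass
class DatasetManifest:
    """Items of a dataset plus their train/val/test assignment."""

    items: list[dict]  # keys: id, image, label; after splitting also: split
    seed: int | None = None

    def split_sizes(self) -> dict[str, int]:
        out = {"train": 0, "val": 0, "test": 0}
        for it in self.items:
            out[it["split"]] += 1
        return out

    def to_csv(self, path) -> None:
        pd.DataFrame(self.items).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DatasetManifest":
        df = pd.read_csv(path)
        return cls(items=df.to_dict("records"))


# ---------------------------------------------------------------------------
# YOLO text I/O
# ---------------------------------------------------------------------------

def read_yolo_labels(path) -> list[Box]:
    """Parse a YOLO ``.txt`` label file: one ``class cx cy w h`` line per box.

    An empty file is a valid image with no targets.  Malformed lines or
    out-of-range coordinates raise ``ValueError`` with the line number.
    """
    boxes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            try:
                cls = int(parts[0])
                cx, cy, w, h = (float(v) for v in parts[1:])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if not all(0.0 <= v <= 1.0 for v in (cx, cy, w, h)):
                raise ValueError(f"{path}:{lineno}: coordinate outside [0, 1]")
            try:
                boxes.append(Box(cls, cx, cy, w, h))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return boxes


def write_yolo_labels(boxes: Sequence[Box], path) -> None:
    """Write boxes as YOLO ``.txt`` lines with 6-decimal coordinates."""
    with open(path, "w") as fh:
        for b in boxes:
            fh.write(f"{b.class_id} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}\n")


def read_predictions(path) -> list[Detection]:
    """Parse a prediction file: one ``class conf cx cy w h`` line per box."""
    dets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
            try:
                cls = int(parts[0])
                conf, cx, cy, w, h = (float(v) for v in parts[1:])
                dets.append(Detection(Box(cls, cx, cy, w, h), conf))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return dets


def write_predictions(dets: Sequence[Detection], path) -> None:
    with open(path, "w") as fh:
        for d in dets:
            b = d.box
            fh.write(
                f"{b.class_id} {d.confidence:.6f} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}\n"
            )


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_dataset(
    manifest: DatasetManifest,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> DatasetManifest:
    """Randomly assign items to train/val/test.

    Sizes follow val = round(r_val·N) (half-up), test = floor(r_test·N),
    train = remainder — the rule that yields 2687/336/335 from 3358 items at
    8:1:1.  The assignment is a seeded uniform shuffle and is deterministic.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    n = len(manifest.items)
    if n < 3:
        raise ValueError("need at least 3 items to form 3 splits")
    n_val = math.floor(ratios[1] * n + 0.5)
    n_test = math.floor(ratios[2] * n)
    n_train = n - n_val - n_test
    if n_train <= 0:
        raise ValueError("ratios leave no training items")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = {}
    for pos, idx in enumerate(perm):
        if pos < n_train:
            assignment[idx] = "train"
        elif pos < n_train + n_val:
            assignment[idx] = "val"
        else:
            assignment[idx] = "test"
    items = [dict(it, split=assignment[i]) for i, it in enumerate(manifest.items)]
    return DatasetManifest(items=items, seed=seed)


# ---------------------------------------------------------------------------
# Geometric augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AffineSpec:
    """Rotation (degrees, counter-clockwise), translation (normalized image
    fractions), and isotropic scale, all about the image center."""

    angle: float = 0.0
    translate: tuple[float, float] = (0.0, 0.0)
    scale: float = 1.0
    min_area: float = 1e-4  # drop boxes smaller than this normalized area


def _clip_box(cls: int, x1, y1, x2, y2, min_area: float) -> Box | None:
    x1, x2 = max(0.0, min(x1, x2)), min(1.0, max(x1, x2))
    y1, y2 = max(0.0, min(y1, y2)), min(1.0, max(y1, y2))
    w, h = x2 - x1, y2 - y1
    if w <= 0 or h <= 0 or w * h < min_area:
        return None
    return Box(cls, (x1 + x2) / 2, (y1 + y2) / 2, w, h)


def affine(limg: LabeledImage, spec: AffineSpec) -> LabeledImage:
    """Rotate/translate/scale raster and boxes about the image center.

    Boxes are re-derived from the axis-aligned extent of their four
    transformed corners, clipped to the image, and dropped when their
    normalized area falls below ``spec.min_area``.
    """
    h, w = limg.image.shape[:2]
    # (x, y) = (col, row) continuous coordinates; rotate about the image center
    center = np.array([w / 2.0, h / 2.0])
    tform = (
        _sktransform.AffineTransform(translation=-center)
        + _sktransform.AffineTransform(rotation=np.deg2rad(spec.angle), scale=spec.scale)
        + _sktransform.AffineTransform(translation=center + np.array([spec.translate[0] * w, spec.translate[1] * h]))
    )
    warped = _sktransform.warp(
        limg.image, tform.inverse, order=1, mode="constant", cval=0.0, preserve_range=True
    ).astype(limg.image.dtype)

    out_boxes = []
    for b in limg.boxes:
        x1, y1, x2, y2 = b.corners
        corners_px = np.array(
            [[x1 * w, y1 * h], [x2 * w, y1 * h], [x2 * w, y2 * h], [x1 * w, y2 * h]]
        )
        tc = tform(corners_px)
        nb = _clip_box(
            b.class_id,
            tc[:, 0].min() / w,
            tc[:, 1].min() / h,
            tc[:, 0].max() / w,
            tc[:, 1].max() / h,
            spec.min_area,
        )
        if nb is not None:
            out_boxes.append(nb)
    return LabeledImage(warped, out_boxes)


# ---------------------------------------------------------------------------
# Photometric augmentation
# ---------------------------------------------------------------------------

def color_distort(
    img: np.ndarray,
    brightness: float = 0.0,
    contrast: float = 1.0,
    saturation: float = 1.0,
    hue: float = 0.0,
) -> np.ndarray:
    """Adjust brightness / contrast / saturation / hue.

    * ``hue`` shifts the HSV hue channel (fraction of a full turn).
    * ``saturation`` multiplies HSV saturation (0 = grayscale).
    * ``contrast`` scales deviations about mid-gray 0.5.
    * ``brightness`` adds a constant on the [0, 1] intensity scale.

    All-identity parameters return the image unchanged.
    """
    x = np.asarray(img).astype(float) / 255.0
    if saturation != 1.0 or hue != 0.0:
        hsv = _skcolor.rgb2hsv(x)
        hsv[..., 0] = (hsv[..., 0] + hue) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] * saturation, 0.0, 1.0)
        x = _skcolor.hsv2rgb(hsv)
    if contrast != 1.0:
        x = (x - 0.5) * contrast + 0.5
    if brightness != 0.0:
        x = x + brightness
    return np.clip(np.round(x * 255.0), 0, 255).astype(np.uint8)


def gaussian_noise(img: np.ndarray, sigma: float, seed: int = 0) -> np.ndarray:
    """Add i.i.d. Gaussian noise, σ on the normalized [0, 1] scale."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return np.asarray(img).copy()
    rng = np.random.default_rng(seed)
    x = np.asarray(img).astype(float) / 255.0
    x = x + rng.normal(0.0, sigma, size=x.shape)
    return np.clip(np.round(x * 255.0), 0, 255).astype(np.uint8)


def cutout(
    limg: LabeledImage,
    n_patches: int,
    patch_size: float = 0.1,
    seed: int = 0,
    drop_occluded: float | None = None,
) -> LabeledImage:
    """Mask ``n_patches`` random rectangles with the image mean color.

    ``patch_size`` is the side length as a fraction of the image height and
    width.  Labels are left untouched (regularization semantics) unless
    ``drop_occluded`` is set, in which case boxes whose area is covered by
    at least that fraction are removed.
    """
    img = limg.image.copy()
    h, w = img.shape[:2]
    ph, pw = max(1, round(patch_size * h)), max(1, round(patch_size * w))
    rng = np.random.default_rng(seed)
    fill = img.reshape(-1, 3).mean(axis=0).round().astype(img.dtype)
    occl = np.zeros((h, w), dtype=bool)
    for _ in range(n_patches):
        top = int(rng.integers(0, h - ph + 1))
        left = int(rng.integers(0, w - pw + 1))
        img[top : top + ph, left : left + pw] = fill
        occl[top : top + ph, left : left + pw] = True
    boxes = list(limg.boxes)
    if drop_occluded is not None:
        kept = []
        for b in boxes:
            x1, y1, x2, y2 = b.corners
            r1, r2 = int(y1 * h), max(int(y1 * h) + 1, int(np.ceil(y2 * h)))
            c1, c2 = int(x1 * w), max(int(x1 * w) + 1, int(np.ceil(x2 * w)))
            frac = occl[r1:r2, c1:c2].mean() if r2 > r1 and c2 > c1 else 0.0
            if frac < drop_occluded:
                kept.append(b)
        boxes = kept
    return LabeledImage(img, boxes)


def mosaic(
    four: Sequence[LabeledImage],
    canvas_size: tuple[int, int],
    jitter: float = 0.1,
    seed: int = 0,
    min_px: int = 2,
    min_area_frac: float = 0.01,
) -> LabeledImage:
    """Compose four labeled images into a 2×2 mosaic about a jittered center.

    The canvas is divided at a center point drawn uniformly within
    ``±jitter`` (normalized) of the midpoint; each source image is resized
    to its quadrant and its boxes are remapped, clipped to the canvas, and
    dropped when the clipped width or height falls below ``min_px`` pixels
    or the clipped area below ``min_area_frac`` of the box's pre-clip area.
    """
    if len(four) != 4:
        raise ValueError("mosaic requires exactly 4 labeled images")
    ch, cw = canvas_size
    rng = np.random.default_rng(seed)
    cx = 0.5 + (rng.uniform(-jitter, jitter) if jitter > 0 else 0.0)
    cy = 0.5 + (rng.uniform(-jitter, jitter) if jitter > 0 else 0.0)
    px = int(round(cx * cw))
    py = int(round(cy * ch))
    px = min(max(px, 1), cw - 1)
    py = min(max(py, 1), ch - 1)

    from PIL import Image as _PILImage

    canvas = np.zeros((ch, cw, 3), dtype=np.uint8)
    # quadrant pixel spans: (top, left, height, width)
    quads = [
        (0, 0, py, px),
        (0, px, py, cw - px),
        (py, 0, ch - py, px),
        (py, px, ch - py, cw - px),
    ]
    out_boxes: list[Box] = []
    for limg, (top, left, qh, qw) in zip(four, quads):
        resized = np.asarray(
            _PILImage.fromarray(limg.image.astype(np.uint8)).resize((qw, qh), _PILImage.BILINEAR)
        )
        canvas[top : top + qh, left : left + qw] = resized
        for b in limg.boxes:
            x1, y1, x2, y2 = b.corners
            nx1 = (left + x1 * qw) / cw
            nx2 = (left + x2 * qw) / cw
            ny1 = (top + y1 * qh) / ch
            ny2 = (top + y2 * qh) / ch
            pre_area = (nx2 - nx1) * (ny2 - ny1)
            cx1, cy1 = max(0.0, nx1), max(0.0, ny1)
            cx2, cy2 = min(1.0, nx2), min(1.0, ny2)
            bw, bh = cx2 - cx1, cy2 - cy1
            if bw * cw < min_px or bh * ch < min_px:
                continue
            if pre_area > 0 and (bw * bh) / pre_area < min_area_frac:
                continue
            out_boxes.append(Box(b.class_id, (cx1 + cx2) / 2, (cy1 + cy2) / 2, bw, bh))
    return LabeledImage(canvas, out_boxes)


#: Parameter bundles emulating field conditions: midday sun, dusk, fog and
#: transmission noise.  Each entry is (operator, kwargs).
ENVIRONMENT_PRESETS = {
    "direct_sun": ("color", {"brightness": 0.18, "saturation": 1.25}),
    "dim": ("color", {"brightness": -0.25, "saturation": 0.8}),
    "fog": ("color", {"contrast": 0.45, "brightness": 0.25}),
    "noise": ("noise", {"sigma": 0.06}),
}


def environment_preset(img: np.ndarray, preset: str, seed: int = 0) -> np.ndarray:
    """Apply one of the environmental simulations (sun / dim / fog / noise).

    Presets are pure parameterizations of :func:`color_distort` and
    :func:`gaussian_noise`: fog reduces contrast and adds haze, dim lowers
    brightness and saturation, direct sun raises both, noise injects
    Gaussian pixel noise.
    """
    if preset not in ENVIRONMENT_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(ENVIRONMENT_PRESETS)}")
    op, kwargs = ENVIRONMENT_PRESETS[preset]
    if op == "color":
        return color_distort(img, **kwargs)
    return gaussian_noise(img, seed=seed, **kwargs)
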