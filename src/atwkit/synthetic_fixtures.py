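"""Synthetic fixtures with known ground truth.

Real Grad-CAM renderings and field detection logs are not bundled with the
package, so every downstream computation is exercised on constructed
inputs whose correct answer is known by design:

* activation fields (sums of Gaussian blobs) rendered through a jet-like
  colormap whose breakpoints hit the four reference anchors exactly;
* detection scenarios with a prescribed number of ground truths, missed
  targets and false detections, laid out on a grid so ground truths never
  overlap and the matching outcome is unambiguous;
* an independent, deliberately naive per-pixel ATW oracle (plain double
  loop) for cross-checking the vectorised metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import color_science
from .atw_metric import ReferenceScheme, default_scheme
from .detection_eval import Box, Detection

__all__ = [
    "ColormapSpec",
    "make_activation_field",
    "apply_colormap",
    "expected_atw",
    "make_detection_scenario",
    "make_background",
    "render_overlay",
]


@dataclass(frozen=True)
class ColormapSpec:
    """Piecewise-linear colormap: ordered breakpoints u → RGB."""

    breakpoints: tuple[tuple[float, tuple[int, int, int]], ...]

    def __post_init__(self):
        us = [u for u, _ in self.breakpoints]
        if len(us) < 2 or us != sorted(us) or len(set(us)) != len(us):
            raise ValueError("breakpoints must be strictly increasing")
        if us[0] != 0.0 or us[-1] != 1.0:
            raise ValueError("breakpoints must span [0, 1]")

    @classmethod
    def jet_like(cls) -> "ColormapSpec":
        """Blue → green → yellow → red, hitting the four reference anchors
        exactly at u = 0, 1/3, 2/3, 1."""
        return cls(
            (
                (0.0, (0, 0, 255)),
                (1.0 / 3.0, (0, 255, 0)),
                (2.0 / 3.0, (255, 255, 0)),
                (1.0, (255, 0, 0)),
            )
        )

    def __call__(self, u):
        """Map intensities in [0, 1] to float RGB (rounded to integers)."""
        u = np.asarray(u, dtype=float)
        us = np.array([p for p, _ in self.breakpoints])
        cols = np.array([c for _, c in self.breakpoints], dtype=float)
        out = np.stack(
            [np.interp(u, us, cols[:, ch]) for ch in range(3)], axis=-1
        )
        return np.round(out)


def make_activation_field(
    shape: tuple[int, int],
    blobs=None,
    seed: int = 0,
    n_random_blobs: int = 3,
) -> np.ndarray:
    """Synthetic activation map: a clamped sum of isotropic Gaussians.

    ``blobs`` is a list of ``((cy, cx), sigma, amplitude)`` with centers and
    widths in normalized [0, 1] coordinates.  When omitted, ``n_random_blobs``
    seeded random blobs are drawn.  Values are clamped to [0, 1].
    """
    h, w = shape
    if blobs is None:
        rng = np.random.default_rng(seed)
        blobs = [
            ((rng.uniform(0.2, 0.8), rng.uniform(0.2, 0.8)),
             rng.uniform(0.05, 0.2),
             rng.uniform(0.4, 1.0))
            for _ in range(n_random_blobs)
        ]
    yy, xx = np.meshgrid(
        (np.arange(h) + 0.5) / h, (np.arange(w) + 0.5) / w, indexing="ij"
    )
    field = np.zeros((h, w))
    for (cy, cx), sigma, amp in blobs:
        field += amp * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)))
    return np.clip(field, 0.0, 1.0)


def apply_colormap(field: np.ndarray, cmap: ColormapSpec | None = None) -> np.ndarray:
    """Render an activation field to an (H, W, 3) uint8 heat-map image."""
    cmap = cmap or ColormapSpec.jet_like()
    field = np.asarray(field, dtype=float)
    if np.any(field < 0) or np.any(field > 1):
        raise ValueError("activation field values must be in [0, 1]")
    return cmap(field).astype(np.uint8)


def expected_atw(
    field: np.ndarray,
    cmap: ColormapSpec | None = None,
    scheme: ReferenceScheme | None = None,
    mask: np.ndarray | None = None,
) -> float:
    """Independent ATW oracle: a plain per-pixel double loop.

    Re-derives the whole chain (colormap → Lab → nearest family →
    within-band weight → mean) with scalar arithmetic, sharing nothing with
    the vectorised implementation beyond the two color-science primitives.
    """
    cmap = cmap or ColormapSpec.jet_like()
    scheme = scheme or default_scheme()
    field = np.asarray(field, dtype=float)
    h, w = field.shape
    if mask is None:
        mask = np.ones((h, w), dtype=bool)

    ordered = scheme.by_rank()
    anchors = [c.lab for c in ordered]
    bands = [c.band for c in ordered]

    total = 0.0
    n = 0
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            rgb = cmap(field[i, j])
            lab = color_science.srgb_to_lab(rgb)
            dists = [color_science.ciede2000(lab, a) for a in anchors]
            # nearest family, ties to the hotter one
            best = 0
            for k in range(1, 4):
                if dists[k] < dists[best] - 1e-9:
                    best = k
            if best == 3:
                wgt = 0.0
            else:
                lo, hi = bands[best]
                d_f, d_n = dists[best], dists[best + 1]
                wgt = hi - (hi - lo) * d_f / (d_f + d_n)
                wgt = min(max(wgt, lo), hi)
            total += wgt
            n += 1
    if n == 0:
        raise ValueError("empty mask")
    return total / n


def make_detection_scenario(
    n_gt: int,
    n_missed: int = 0,
    n_false: int = 0,
    iou_noise: float = 0.05,
    seed: int = 0,
) -> tuple[list[Box], list[Detection]]:
    """Detection scenario with a prescribed matching outcome.

    Places ``n_gt`` ground-truth boxes in distinct cells of a regular grid
    (so distinct ground truths never overlap), emits jittered detections
    for all but ``n_missed`` of them (jitter bounded so IoU with the parent
    box stays well above 0.5) and ``n_false`` detections centered in unused
    grid cells, disjoint from every ground truth.

    Under greedy matching at IoU 0.5 the outcome is exactly
    ``tp = n_gt − n_missed``, ``fp = n_false``, ``fn = n_missed``.
    """
    if n_missed > n_gt:
        raise ValueError("cannot miss more targets than exist")
    if not (0.0 <= iou_noise <= 0.15):
        raise ValueError("iou_noise must be in [0, 0.15]")
    rng = np.random.default_rng(seed)
    n_cells_needed = n_gt + n_false
    g = int(np.ceil(np.sqrt(n_cells_needed)))
    cell = 1.0 / g
    size = 0.4 * cell  # box side; gap ≥ 0.6·cell between neighbors → IoU 0

    cells = rng.permutation(g * g)[:n_cells_needed]
    centers = [((c // g + 0.5) * cell, (c % g + 0.5) * cell) for c in cells]

    gts = [Box(0, cx, cy, size, size) for cy, cx in centers[:n_gt]]
    detected_idx = rng.permutation(n_gt)[: n_gt - n_missed]

    dets: list[Detection] = []
    for i in sorted(detected_idx):
        b = gts[i]
        # shift ≤ iou_noise·size per axis keeps IoU ≥ ((1-q)²)/(2-(1-q)²) > 0.5
        dx = rng.uniform(-iou_noise, iou_noise) * b.w
        dy = rng.uniform(-iou_noise, iou_noise) * b.h
        conf = float(rng.uniform(0.55, 0.99))
        dets.append(Detection(Box(0, b.cx + dx, b.cy + dy, b.w, b.h), conf))
    for cy, cx in centers[n_gt:]:
        conf = float(rng.uniform(0.5, 0.95))
        dets.append(Detection(Box(0, cx, cy, size, size), conf))
    return gts, dets


def make_background(shape: tuple[int, int], seed: int = 0) -> np.ndarray:
    """Greenish textured raster standing in for a field photograph
    (synthetic; no real imagery is bundled)."""
    rng = np.random.default_rng(seed)
    h, w = shape
    base = np.empty((h, w, 3), dtype=float)
    base[..., 0] = 90
    base[..., 1] = 130
    base[..., 2] = 70
    base += rng.normal(0.0, 18.0, size=(h, w, 1))
    return np.clip(np.round(base), 0, 255).astype(np.uint8)


def render_overlay(
    heatmap: np.ndarray,
    background: np.ndarray,
    alpha: float,
    heat_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Alpha-blend a heat map over a background raster.

    Returns the blended image and the ground-truth foreground mask
    (``heat_mask`` if given, else all-true).  ``alpha = 1`` reproduces the
    heat map, ``alpha = 0`` the background.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    hm = np.asarray(heatmap, dtype=float)
    bg = np.asarray(background, dtype=float)
    if hm.shape != bg.shape:
        raise ValueError("heatmap and background shapes differ")
    out = np.clip(np.round(alpha * hm + (1.0 - alpha) * bg), 0, 255).astype(np.uint8)
    if heat_mask is None:
        heat_mask = np.ones(hm.shape[:2], dtype=bool)
    return out, np.asarray(heat_mask, dtype=bool)
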