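"""Average Temperature Weight (ATW): a scalar summary of a class-activation
heat map.

A Grad-CAM style heat map encodes feature importance as color temperature:
red regions are "hot" (strongly attended), blue regions "cold".  ATW reduces
such a map to one number in [0, 1]:

1. segment the foreground (the thermally active region);
2. convert every foreground pixel from sRGB to CIELAB;
3. assign each pixel to the nearest of four reference anchor colors
   (red, yellow, green, blue) under the CIEDE2000 distance;
4. interpolate a temperature weight inside the family's band —
   red [0.8, 1.0], yellow [0.6, 0.8], green [0.4, 0.6], blue fixed at 0;
5. average the per-pixel weights over the foreground.

The within-family weight is a distance-ratio blend between the family's
anchor and the adjacent cooler anchor: for family f with band [lo, hi],

    w = hi − (hi − lo) · d_f / (d_f + d_next)

where d_f is the ΔE00 distance to f's anchor and d_next the distance to the
next cooler anchor (red→yellow, yellow→green, green→blue), clamped to
[lo, hi].  The weight is continuous within a family and reaches the band's
upper bound exactly at the anchor.  Blue is identically 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .color_science import ciede2000, srgb_to_lab

__all__ = [
    "ReferenceColor",
    "ReferenceScheme",
    "ATWResult",
    "AtwComparison",
    "default_scheme",
    "segment_foreground",
    "nearest_family",
    "pixel_weight",
    "pixel_weight_field",
    "compute_atw",
    "compare_atw",
]

#: ΔE00 slack below which two anchor distances count as a tie.
TIE_TOL = 1e-9

#: Default ΔE00 radius for the anchor-proximity segmentation strategy.
DEFAULT_TAU = 30.0


@dataclass(frozen=True)
class ReferenceColor:
    """One reference anchor: a color family with its temperature-weight band.

    ``hot_rank`` orders the families from hottest (0 = red) to coldest
    (3 = blue); the within-family interpolation uses the next-cooler anchor.
    """

    name: str
    rgb: tuple[int, int, int]
    band: tuple[float, float]
    hot_rank: int

    def __post_init__(self):
        lo, hi = self.band
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"band must satisfy 0 <= lo <= hi <= 1, got {self.band}")
        if any(not (0 <= v <= 255) for v in self.rgb):
            raise ValueError(f"RGB channel outside [0, 255]: {self.rgb}")

    @property
    def lab(self) -> np.ndarray:
        return srgb_to_lab(self.rgb)


@dataclass(frozen=True)
class ReferenceScheme:
    """The ordered set of four reference colors (the set C of the metric)."""

    colors: tuple[ReferenceColor, ...]

    def __post_init__(self):
        if len(self.colors) != 4:
            raise ValueError("a reference scheme has exactly 4 colors")
        ranks = sorted(c.hot_rank for c in self.colors)
        if ranks != [0, 1, 2, 3]:
            raise ValueError("hot_ranks must be a permutation of 0..3")
        rgbs = {c.rgb for c in self.colors}
        if len(rgbs) != 4:
            raise ValueError("anchor colors must be pairwise distinct")

    def by_rank(self) -> tuple[ReferenceColor, ...]:
        """Colors ordered hottest → coldest."""
        return tuple(sorted(self.colors, key=lambda c: c.hot_rank))

    @property
    def anchors_lab(self) -> np.ndarray:
        """(4, 3) Lab anchors, ordered by hot_rank."""
        return np.stack([c.lab for c in self.by_rank()])

    @property
    def bands(self) -> np.ndarray:
        """(4, 2) weight bands, ordered by hot_rank."""
        return np.array([c.band for c in self.by_rank()])

    @classmethod
    def from_yaml(cls, path) -> "ReferenceScheme":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        try:
            colors = tuple(
                ReferenceColor(
                    name=c["name"],
                    rgb=tuple(int(v) for v in c["rgb"]),
                    band=tuple(float(v) for v in c["band"]),
                    hot_rank=int(c["hot_rank"]),
                )
                for c in doc["colors"]
            )
        except (KeyError, TypeError) as exc:
            raise ValueError(f"malformed scheme file {path}: {exc}") from exc
        return cls(colors)

    def to_yaml(self, path) -> None:
        doc = {
            "colors": [
                {
                    "name": c.name,
                    "rgb": list(c.rgb),
                    "band": list(c.band),
                    "hot_rank": c.hot_rank,
                }
                for c in self.colors
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def default_scheme() -> ReferenceScheme:
    """Pure-hue anchors with the standard temperature bands.

    Red (255,0,0) band [0.8, 1.0]; yellow (255,255,0) [0.6, 0.8];
    green (0,255,0) [0.4, 0.6]; blue (0,0,255) weight 0.
    """
    return ReferenceScheme(
        (
            ReferenceColor("red", (255, 0, 0), (0.8, 1.0), 0),
            ReferenceColor("yellow", (255, 255, 0), (0.6, 0.8), 1),
            ReferenceColor("green", (0, 255, 0), (0.4, 0.6), 2),
            ReferenceColor("blue", (0, 0, 255), (0.0, 0.0), 3),
        )
    )


@dataclass
class ATWResult:
    """ATW of one heat map plus its per-family decomposition."""

    atw: float
    n_foreground: int
    family_counts: dict[str, int]
    family_mean_weights: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "atw": self.atw,
            "n_foreground": self.n_foreground,
            "family_counts": self.family_counts,
            "family_mean_weights": self.family_mean_weights,
        }


@dataclass
class AtwComparison:
    """Baseline vs improved ATW: absolute gain in percentage points and
    relative enhancement in percent (None when the baseline is 0)."""

    delta_pp: float
    relative_pct: float | None


def _as_image(img) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {arr.shape}")
    return arr


def _anchor_distances(lab: np.ndarray, scheme: ReferenceScheme) -> np.ndarray:
    """(..., 4) ΔE00 from each pixel to the anchors, hottest first."""
    return ciede2000(lab[..., None, :], scheme.anchors_lab)


def _family_index(dists: np.ndarray) -> np.ndarray:
    """Nearest-anchor index with ties (within TIE_TOL) going to the hotter
    family.  ``dists`` is (..., 4) ordered hottest → coldest."""
    dmin = dists.min(axis=-1, keepdims=True)
    eligible = dists <= dmin + TIE_TOL
    return np.argmax(eligible, axis=-1)  # first True = lowest hot_rank


def _weights_from_distances(dists: np.ndarray, fam: np.ndarray, scheme: ReferenceScheme) -> np.ndarray:
    bands = scheme.bands
    lo = bands[fam, 0]
    hi = bands[fam, 1]
    # next-cooler anchor; blue (last) has no successor and is handled below
    nxt = np.minimum(fam + 1, 3)
    d_f = np.take_along_axis(dists, fam[..., None], axis=-1)[..., 0]
    d_n = np.take_along_axis(dists, nxt[..., None], axis=-1)[..., 0]
    denom = d_f + d_n
    ratio = np.divide(d_f, denom, out=np.zeros_like(d_f), where=denom > 0)
    w = hi - (hi - lo) * ratio
    w = np.clip(w, lo, hi)
    return np.where(fam == 3, 0.0, w)


def segment_foreground(
    img,
    strategy: str = "full",
    mask=None,
    tau: float = DEFAULT_TAU,
    scheme: ReferenceScheme | None = None,
) -> np.ndarray:
    """Boolean foreground mask for ATW.

    Strategies
    ----------
    full
        Keep every pixel (identity mask).
    external
        Use a supplied mask of matching shape.
    anchor_proximity
        Keep pixels whose minimum ΔE00 to any anchor is ≤ ``tau``; this
        drops background colors (whites, grays, photo content) that are far
        from every heat-map hue.

    Raises
    ------
    ValueError
        If the resulting mask is empty (ATW is undefined for N = 0), or the
        external mask is missing/mis-shaped.
    """
    arr = _as_image(img)
    h, w = arr.shape[:2]
    if strategy == "full":
        out = np.ones((h, w), dtype=bool)
    elif strategy == "external":
        if mask is None:
            raise ValueError("strategy='external' requires a mask")
        out = np.asarray(mask, dtype=bool)
        if out.shape != (h, w):
            raise ValueError(f"mask shape {out.shape} does not match image {(h, w)}")
    elif strategy == "anchor_proximity":
        scheme = scheme or default_scheme()
        lab = srgb_to_lab(arr.astype(float))
        dists = _anchor_distances(lab, scheme)
        out = dists.min(axis=-1) <= tau
    else:
        raise ValueError(f"unknown segmentation strategy {strategy!r}")
    if not out.any():
        raise ValueError("empty foreground mask: ATW is undefined (N = 0)")
    return out


def nearest_family(pixel_lab, scheme: ReferenceScheme | None = None):
    """Family of the nearest anchor for one Lab pixel.

    Returns ``(family_name, distances)`` where ``distances`` maps each
    family name to its ΔE00.  Exact ties go to the hotter family.
    """
    scheme = scheme or default_scheme()
    lab = np.asarray(pixel_lab, dtype=float)
    dists = _anchor_distances(lab, scheme)
    idx = int(_family_index(dists))
    ordered = scheme.by_rank()
    return ordered[idx].name, {c.name: float(d) for c, d in zip(ordered, dists)}


def pixel_weight(pixel_lab, scheme: ReferenceScheme | None = None) -> float:
    """Temperature weight in [0, 1] of a single Lab pixel."""
    scheme = scheme or default_scheme()
    lab = np.asarray(pixel_lab, dtype=float)
    dists = _anchor_distances(lab, scheme)
    fam = _family_index(dists)
    return float(_weights_from_distances(dists, fam, scheme))


def pixel_weight_field(img, scheme: ReferenceScheme | None = None):
    """Per-pixel temperature weights and family assignment of a heat map.

    Returns ``(weights, family_index)``: an (H, W) float field in [0, 1] and
    an (H, W) int field indexing families hottest → coldest.
    """
    scheme = scheme or default_scheme()
    arr = _as_image(img)
    lab = srgb_to_lab(arr.astype(float))
    dists = _anchor_distances(lab, scheme)
    fam = _family_index(dists)
    return _weights_from_distances(dists, fam, scheme), fam


def compute_atw(img, mask=None, scheme: ReferenceScheme | None = None) -> ATWResult:
    """ATW of a heat map: mean temperature weight over the foreground.

    ``mask`` defaults to the full image.  Raises ``ValueError`` on an empty
    mask (the metric is undefined for zero foreground pixels).
    """
    scheme = scheme or default_scheme()
    arr = _as_image(img)
    if mask is None:
        mask = np.ones(arr.shape[:2], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != arr.shape[:2]:
        raise ValueError(f"mask shape {mask.shape} does not match image {arr.shape[:2]}")
    if not mask.any():
        raise ValueError("empty foreground mask: ATW is undefined (N = 0)")

    weights, fam = pixel_weight_field(arr, scheme)
    w = weights[mask]
    f = fam[mask]
    names = [c.name for c in scheme.by_rank()]
    counts = {}
    means = {}
    for i, name in enumerate(names):
        sel = f == i
        counts[name] = int(sel.sum())
        means[name] = float(w[sel].mean()) if sel.any() else 0.0
    return ATWResult(
        atw=float(w.mean()),
        n_foreground=int(mask.sum()),
        family_counts=counts,
        family_mean_weights=means,
    )


def compare_atw(baseline, improved) -> AtwComparison:
    """Gain of an improved heat map over a baseline.

    Accepts ``ATWResult`` objects or plain ATW floats.  Returns the absolute
    difference in percentage points and the relative enhancement in percent
    (None when the baseline ATW is 0, where the ratio is undefined).
    """
    b = baseline.atw if isinstance(baseline, ATWResult) else float(baseline)
    i = improved.atw if isinstance(improved, ATWResult) else float(improved)
    delta_pp = 100.0 * (i - b)
    relative = None if b == 0 else 100.0 * (i - b) / b
    return AtwComparison(delta_pp=delta_pp, relative_pct=relative)
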