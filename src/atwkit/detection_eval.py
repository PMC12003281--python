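"""Object-detection evaluation: IoU, greedy matching, precision / recall /
F1, all-point-interpolated AP at IoU 0.5, and field-trial accounting
(missed- and false-detection rates over a known number of targets).

Boxes follow the YOLO text convention: normalized center/size in [0, 1]
with the origin at the top-left.  Matching is class-aware, greedy in
descending confidence (ties by input order), each detection taking the
unmatched ground truth of highest IoU ≥ the threshold (IoU ties to the
lower ground-truth index).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Box",
    "Detection",
    "EvalCounts",
    "Metrics",
    "FieldCounts",
    "iou",
    "match_detections",
    "precision",
    "recall",
    "f1",
    "average_precision",
    "mean_average_precision",
    "evaluate",
    "field_counts",
]


@dataclass(frozen=True)
class Box:
    """Normalized center-format bounding box (YOLO convention)."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise ValueError(f"box center outside [0,1]²: ({self.cx}, {self.cy})")
        if not (0.0 < self.w <= 1.0 and 0.0 < self.h <= 1.0):
            raise ValueError(f"box size must be in (0,1]: ({self.w}, {self.h})")

    @property
    def corners(self) -> tuple[float, float, float, float]:
        """(x1, y1, x2, y2)."""
        return (
            self.cx - self.w / 2,
            self.cy - self.h / 2,
            self.cx + self.w / 2,
            self.cy + self.h / 2,
        )

    @property
    def area(self) -> float:
        return self.w * self.h


@dataclass(frozen=True)
class Detection:
    box: Box
    confidence: float

    def __post_init__(self):
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence outside [0,1]: {self.confidence}")


@dataclass
class EvalCounts:
    """True-positive / false-positive / false-negative bookkeeping."""

    tp: int
    fp: int
    fn: int


@dataclass
class Metrics:
    precision: float
    recall: float
    f1: float
    ap50: float
    map50: float


@dataclass
class FieldCounts:
    """Field-trial accounting over a test set with a known target count.

    ``detected`` counts every emitted detection (correct + false):
    detected = (n_gt − missed) + false_dets.  Rates are percentages of the
    ground-truth count, rounded half-up to one decimal place.
    """

    n_gt: int
    detected: int
    missed: int
    false_dets: int
    missed_rate_pct: float
    false_rate_pct: float


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint."""
    ax1, ay1, ax2, ay2 = a.corners
    bx1, by1, bx2, by2 = b.corners
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


def _iou_matrix(dets: Sequence[Detection], gts: Sequence[Box]) -> np.ndarray:
    """(n_det, n_gt) IoU matrix, zeroed across class mismatches."""
    nd, ng = len(dets), len(gts)
    if nd == 0 or ng == 0:
        return np.zeros((nd, ng))
    d = np.array([list(det.box.corners) for det in dets])
    g = np.array([list(gt.corners) for gt in gts])
    iw = np.minimum(d[:, None, 2], g[None, :, 2]) - np.maximum(d[:, None, 0], g[None, :, 0])
    ih = np.minimum(d[:, None, 3], g[None, :, 3]) - np.maximum(d[:, None, 1], g[None, :, 1])
    inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
    da = (d[:, 2] - d[:, 0]) * (d[:, 3] - d[:, 1])
    ga = (g[:, 2] - g[:, 0]) * (g[:, 3] - g[:, 1])
    mat = inter / (da[:, None] + ga[None, :] - inter)
    dcls = np.array([det.box.class_id for det in dets])
    gcls = np.array([gt.class_id for gt in gts])
    mat[dcls[:, None] != gcls[None, :]] = 0.0
    return mat


def match_detections(
    dets: Sequence[Detection],
    gts: Sequence[Box],
    iou_thr: float = 0.5,
) -> tuple[EvalCounts, list[tuple[int, int]]]:
    """Greedy one-to-one matching of detections to ground truths.

    Detections are processed in descending confidence (stable: equal
    confidences keep input order); each takes the unmatched same-class
    ground truth of highest IoU ≥ ``iou_thr`` (ties: lower GT index).

    Returns the TP/FP/FN counts and the matched (det_index, gt_index) pairs.
    """
    if not (0.0 < iou_thr <= 1.0):
        raise ValueError(f"iou_thr must be in (0, 1], got {iou_thr}")
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    mat = _iou_matrix(dets, gts)
    gt_taken = np.zeros(len(gts), dtype=bool)
    matches: list[tuple[int, int]] = []
    for di in order:
        best_j, best_iou = -1, iou_thr
        for j in range(len(gts)):
            if gt_taken[j]:
                continue
            v = mat[di, j]
            if v > best_iou or (v == best_iou and v >= iou_thr and best_j == -1):
                best_j, best_iou = j, v
        if best_j >= 0:
            gt_taken[best_j] = True
            matches.append((di, best_j))
    tp = len(matches)
    counts = EvalCounts(tp=tp, fp=len(dets) - tp, fn=len(gts) - tp)
    return counts, matches


def precision(tp: int, fp: int) -> float:
    """Fraction of detections that are correct; 0 when no detections."""
    return tp / (tp + fp) if tp + fp > 0 else 0.0


def recall(tp: int, fn: int) -> float:
    """Fraction of ground truths found; 0 when no ground truths."""
    return tp / (tp + fn) if tp + fn > 0 else 0.0


def f1(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0.0 <= p <= 1.0 and 0.0 <= r <= 1.0):
        raise ValueError("precision and recall must be in [0, 1]")
    return 2.0 * p * r / (p + r) if p + r > 0 else 0.0


def average_precision(
    dets: Sequence[Detection],
    gts: Sequence[Box],
    iou_thr: float = 0.5,
    interpolation: str = "all_point",
) -> float:
    """All-point-interpolated average precision at the given IoU threshold.

    Detections are ranked by confidence; the precision-recall staircase is
    replaced by its monotone (from the right) envelope and integrated over
    recall.  ``interpolation='eleven_point'`` gives the legacy 11-point
    variant.  Raises on empty ground truth (AP undefined).
    """
    if len(gts) == 0:
        raise ValueError("average precision is undefined without ground truth")
    if len(dets) == 0:
        return 0.0
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    mat = _iou_matrix(dets, gts)
    gt_taken = np.zeros(len(gts), dtype=bool)
    tp_flags = np.zeros(len(dets), dtype=bool)
    for rank, di in enumerate(order):
        best_j, best_iou = -1, iou_thr
        for j in range(len(gts)):
            if gt_taken[j]:
                continue
            v = mat[di, j]
            if v > best_iou or (v == best_iou and v >= iou_thr and best_j == -1):
                best_j, best_iou = j, v
        if best_j >= 0:
            gt_taken[best_j] = True
            tp_flags[rank] = True
    cum_tp = np.cumsum(tp_flags)
    cum_fp = np.cumsum(~tp_flags)
    rec = cum_tp / len(gts)
    prec = cum_tp / (cum_tp + cum_fp)
    if interpolation == "all_point":
        mrec = np.concatenate([[0.0], rec])
        mprec = np.concatenate([[1.0], prec])
        mprec = np.maximum.accumulate(mprec[::-1])[::-1]
        return float(np.sum((mrec[1:] - mrec[:-1]) * mprec[1:]))
    if interpolation == "eleven_point":
        pts = []
        for r0 in np.linspace(0.0, 1.0, 11):
            mask = rec >= r0
            pts.append(prec[mask].max() if mask.any() else 0.0)
        return float(np.mean(pts))
    raise ValueError(f"unknown interpolation {interpolation!r}")


def mean_average_precision(
    dets: Sequence[Detection],
    gts: Sequence[Box],
    iou_thr: float = 0.5,
) -> float:
    """mAP at the given IoU threshold: mean of per-class AP over the classes
    present in the ground truth.  Equals AP for single-class data."""
    classes = sorted({g.class_id for g in gts})
    if not classes:
        raise ValueError("mAP is undefined without ground truth")
    aps = []
    for c in classes:
        c_gts = [g for g in gts if g.class_id == c]
        c_dets = [d for d in dets if d.box.class_id == c]
        aps.append(average_precision(c_dets, c_gts, iou_thr))
    return float(np.mean(aps))


def evaluate(
    dets: Sequence[Detection],
    gts: Sequence[Box],
    iou_thr: float = 0.5,
) -> Metrics:
    """Full metric set at one IoU threshold."""
    counts, _ = match_detections(dets, gts, iou_thr)
    p = precision(counts.tp, counts.fp)
    r = recall(counts.tp, counts.fn)
    classes = {g.class_id for g in gts}
    ap = average_precision(dets, gts, iou_thr) if len(classes) <= 1 and gts else 0.0
    m = mean_average_precision(dets, gts, iou_thr) if gts else 0.0
    if len(classes) <= 1:
        ap = m
    return Metrics(precision=p, recall=r, f1=f1(p, r), ap50=ap, map50=m)


def _round_half_up(x: float, decimals: int = 1) -> float:
    scale = 10**decimals
    return math.floor(x * scale + 0.5) / scale


def field_counts(n_gt: int, counts: EvalCounts) -> FieldCounts:
    """Field-trial accounting over ``n_gt`` known targets.

    detected = (n_gt − fn) + fp; missed and false rates are fn/n_gt and
    fp/n_gt as percentages rounded half-up to one decimal place.
    """
    if n_gt <= 0:
        raise ValueError("n_gt must be positive")
    missed = counts.fn
    false_dets = counts.fp
    detected = (n_gt - missed) + false_dets
    return FieldCounts(
        n_gt=n_gt,
        detected=detected,
        missed=missed,
        false_dets=false_dets,
        missed_rate_pct=_round_half_up(100.0 * missed / n_gt),
        false_rate_pct=_round_half_up(100.0 * false_dets / n_gt),
    )
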