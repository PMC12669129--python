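"""Plant detection contract, a classical reference detector, and evaluation.

The pipeline treats detection as pluggable: anything returning a list of
:class:`Box` per frame satisfies the contract, whether it is the classical
foliage detector below, a replay of ground-truth boxes, or an external neural
detector whose output is read from CSV.  The evaluation half implements the
standard detection metrics — IoU, greedy one-to-one matching, the
F1–confidence sweep used to pick an operating threshold, and all-point
interpolated average precision / mAP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

__all__ = [
    "Box",
    "MatchResult",
    "iou",
    "match",
    "precision_recall",
    "f1_confidence_curve",
    "average_precision",
    "mean_average_precision",
    "reference_detect",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned pixel rectangle, origin top-left, y downward.

    Crop extraction uses the half-open integer convention
    ``[floor(x1), ceil(x2)) x [floor(y1), ceil(y2))``.
    """

    x1: float
    y1: float
    x2: float
    y2: float
    conf: float = 1.0

    def __post_init__(self) -> None:
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValueError(f"degenerate box {(self.x1, self.y1, self.x2, self.y2)}")

    @property
    def area(self) -> float:
        return (self.x2 - self.x1) * (self.y2 - self.y1)

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x1 + self.x2) / 2.0, (self.y1 + self.y2) / 2.0)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x1, self.y1, self.x2, self.y2)


def as_box(b, conf: float = 1.0) -> Box:
    """Coerce a 4-tuple or Box to a Box."""
    if isinstance(b, Box):
        return b
    return Box(*b, conf=conf)


@dataclass
class MatchResult:
    """Outcome of matching predictions against ground truth at one IoU cut."""

    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 1.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 1.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def iou(a, b) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint, 1 iff equal."""
    a, b = as_box(a), as_box(b)
    ix = min(a.x2, b.x2) - max(a.x1, b.x1)
    iy = min(a.y2, b.y2) - max(a.y1, b.y1)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def match(preds, truths, iou_thresh: float = 0.5) -> MatchResult:
    """Greedy one-to-one matching, confidence-descending.

    Each prediction (highest confidence first) claims the unmatched truth box
    of largest IoU, provided that IoU reaches ``iou_thresh``; every truth is
    matched at most once.  ``tp + fn = |truths|`` and ``tp + fp = |preds|``
    hold by construction.
    """
    if not (0.0 < iou_thresh <= 1.0):
        raise ValueError("iou_thresh must be in (0, 1]")
    preds = [as_box(p) for p in preds]
    truths = [as_box(t) for t in truths]
    order = sorted(range(len(preds)), key=lambda i: -preds[i].conf)
    taken = [False] * len(truths)
    pairs: list[tuple[int, int, float]] = []
    for pi in order:
        best_j, best_iou = -1, iou_thresh
        for tj, t in enumerate(truths):
            if taken[tj]:
                continue
            v = iou(preds[pi], t)
            if v >= best_iou and v > 0:
                if v > best_iou or best_j < 0:
                    best_j, best_iou = tj, v
        if best_j >= 0:
            taken[best_j] = True
            pairs.append((pi, best_j, best_iou))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(preds) - tp, fn=len(truths) - tp, pairs=pairs)


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float]:
    """Precision and recall from raw confusion counts."""
    return MatchResult(tp, fp, fn).precision, MatchResult(tp, fp, fn).recall


def f1_confidence_curve(preds_per_image, truths_per_image, iou_thresh: float = 0.5):
    """F1 as a function of the confidence cut-off.

    Sweeps every observed confidence (predictions with ``conf >= cut`` are
    kept) and returns ``(curve, best_threshold)`` where ``curve`` is a list of
    ``(threshold, f1)`` and the argmax threshold breaks F1 ties toward the
    highest threshold.
    """
    all_preds = [[as_box(p) for p in preds] for preds in preds_per_image]
    n_truth = sum(len(t) for t in truths_per_image)
    if n_truth == 0:
        raise ValueError("F1 undefined: no ground-truth boxes")
    confs = sorted({p.conf for preds in all_preds for p in preds})
    if not confs:
        raise ValueError("need at least one prediction")
    curve = []
    for cut in confs:
        tp = fp = fn = 0
        for preds, truths in zip(all_preds, truths_per_image):
            kept = [p for p in preds if p.conf >= cut]
            m = match(kept, truths, iou_thresh)
            tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
        curve.append((cut, MatchResult(tp, fp, fn).f1))
    best = max(curve, key=lambda tf: (tf[1], tf[0]))[0]
    return curve, best


def average_precision(preds_per_image, truths_per_image, iou_thresh: float = 0.5) -> float:
    """All-point interpolated AP at one IoU threshold.

    Predictions are ranked by confidence across the corpus; each is a TP if
    it claims a not-yet-matched truth box in its own image at IoU >=
    threshold.  AP integrates the interpolated precision envelope over the
    exact recall steps (no sampling grid).
    """
    flat = []  # (conf, image_idx, Box)
    for img_i, preds in enumerate(preds_per_image):
        for p in preds:
            p = as_box(p)
            flat.append((p.conf, img_i, p))
    n_truth = sum(len(t) for t in truths_per_image)
    if n_truth == 0:
        return 0.0
    flat.sort(key=lambda t: -t[0])
    taken = [np.zeros(len(t), dtype=bool) for t in truths_per_image]
    tp_flags = np.zeros(len(flat), dtype=bool)
    for k, (_conf, img_i, p) in enumerate(flat):
        truths = truths_per_image[img_i]
        best_j, best_iou = -1, iou_thresh
        for tj, t in enumerate(truths):
            if taken[img_i][tj]:
                continue
            v = iou(p, t)
            if v >= best_iou and (v > best_iou or best_j < 0):
                best_j, best_iou = tj, v
        if best_j >= 0:
            taken[img_i][best_j] = True
            tp_flags[k] = True
    if not len(flat):
        return 0.0
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(~tp_flags)
    recall = tp_cum / n_truth
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope (non-increasing from the right), then step integration
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, prec_env):
        if r > r_prev:
            ap += (r - r_prev) * p
            r_prev = r
    return float(ap)


def mean_average_precision(preds_per_image, truths_per_image, iou_grid=None) -> float:
    """mAP over an IoU grid; default grid is 0.50:0.95 step 0.05 (10 cuts)."""
    if iou_grid is None:
        iou_grid = np.arange(0.50, 0.96, 0.05)
    return float(np.mean([average_precision(preds_per_image, truths_per_image, t) for t in iou_grid]))


# ---------------------------------------------------------------------------
# classical reference detector
# ---------------------------------------------------------------------------

def reference_detect(image: np.ndarray, min_area_px: int = 60, reference_area: float = 150.0):
    """Detect green foliage regions in a top-view bed image.

    Tint-robust segmentation: each channel is first normalised by its image
    mean (undoing multiplicative LED colour casts), then an excess-green
    index ``2g - r - b`` is thresholded; connected components above
    ``min_area_px`` become tight boxes with ``conf = min(1, area /
    reference_area)``, sorted by confidence descending.  Near-black
    (dark-period) frames yield no detections.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("reference_detect needs an HxWx3 RGB raster")
    img = image.astype(np.float64)
    if img.mean() < 12.0:  # dark-period frame: nothing to segment
        return []
    means = img.reshape(-1, 3).mean(axis=0)
    means = np.where(means < 1e-6, 1.0, means)
    norm = img / means
    exg = 2.0 * norm[..., 1] - norm[..., 0] - norm[..., 2]
    mask = exg > 0.45
    labels = measure.label(mask, connectivity=2)
    boxes = []
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        r0, c0, r1, c1 = region.bbox  # half-open rows/cols
        boxes.append(Box(float(c0), float(r0), float(c1), float(r1),
                         conf=min(1.0, region.area / reference_area)))
    boxes.sort(key=lambda b: -b.conf)
    return boxes
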