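"""Detection post-processing: confidence cut, nested-box removal, the
exact-count skip rule, and K-means row ordering.

A bed frame only enters the dataset when the detector, after thresholding at
the operating confidence and removing nested boxes, returns exactly the
expected number of plants; otherwise the frame is skipped and logged.  The
survivors are assigned a stable reading order: 1-D K-means on the box-centre
vertical coordinate groups plants into rows, rows are ranked top to bottom,
and plants within a row are sorted left to right.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detect import Box, as_box

__all__ = [
    "Center",
    "OrderedLayout",
    "filter_confidence",
    "remove_nested",
    "enforce_count",
    "order_instances",
    "kmeans_1d",
]


@dataclass(frozen=True)
class Center:
    """Box centre ``(cx, cy) = ((x1+x2)/2, (y1+y2)/2)``."""

    cx: float
    cy: float

    @classmethod
    def of(cls, box) -> "Center":
        b = as_box(box)
        return cls((b.x1 + b.x2) / 2.0, (b.y1 + b.y2) / 2.0)


@dataclass
class OrderedLayout:
    """Boxes in final label order plus per-box row index, or a skip mark.

    ``skip_reason`` is ``None`` for usable frames, ``"wrong_count"`` when the
    detector did not return exactly the expected number of plants, and
    ``"degenerate_rows"`` when row clustering produced an empty row.
    """

    boxes: list[Box] = field(default_factory=list)
    row_of: list[int] = field(default_factory=list)
    skip_reason: str | None = None

    @property
    def skipped(self) -> bool:
        return self.skip_reason is not None


def filter_confidence(boxes, threshold: float):
    """Keep boxes with confidence strictly above ``threshold``, order kept."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    return [b for b in (as_box(x) for x in boxes) if b.conf > threshold]


def _nested_in(a: Box, b: Box, tol: float) -> bool:
    """Is ``a`` inside ``b`` expanded by ``tol`` on all four sides?"""
    return (
        a.x1 >= b.x1 - tol
        and a.y1 >= b.y1 - tol
        and a.x2 <= b.x2 + tol
        and a.y2 <= b.y2 + tol
    )


def remove_nested(boxes, tolerance_px: float = 10.0):
    """Drop every box nested (within a pixel tolerance) inside a larger kept box.

    Boxes are processed largest-area first; ties on area keep the
    higher-confidence box.  A box is removed iff some kept box of at least
    its area contains it once grown by ``tolerance_px`` on each side.  The
    result is idempotent and pairwise non-nested at the given tolerance.
    Original relative order of the survivors is preserved.
    """
    if tolerance_px < 0:
        raise ValueError("tolerance_px must be >= 0")
    boxes = [as_box(b) for b in boxes]
    order = sorted(range(len(boxes)), key=lambda i: (-boxes[i].area, -boxes[i].conf, i))
    kept_idx: list[int] = []
    for i in order:
        if any(_nested_in(boxes[i], boxes[j], tolerance_px) for j in kept_idx):
            continue
        kept_idx.append(i)
    kept_idx.sort()
    return [boxes[i] for i in kept_idx]


def enforce_count(boxes, expected: int) -> OrderedLayout:
    """Pass the frame iff exactly ``expected`` boxes remain; else skip it."""
    if expected < 1:
        raise ValueError("expected count must be >= 1")
    boxes = [as_box(b) for b in boxes]
    if len(boxes) != expected:
        return OrderedLayout(boxes=boxes, row_of=[], skip_reason="wrong_count")
    return OrderedLayout(boxes=boxes, row_of=[], skip_reason=None)


def kmeans_1d(values, k: int, seed: int = 0, max_iter: int = 100):
    """Exact 1-D K-means by dynamic programming.

    In one dimension the optimal sum-of-squares clustering is contiguous in
    sorted order, so the global optimum is found by DP over split points —
    deterministic, independent of input order and of the seed (kept in the
    signature for interface stability), and free of the local optima Lloyd
    iterations can hit on uneven row sizes.  Returns ``(labels, centroids)``
    with cluster indices ordered by ascending centroid.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 1:
        raise ValueError("kmeans_1d expects a 1-D array")
    n = len(values)
    if k < 1 or n < k:
        raise ValueError("need at least k values")
    order = np.argsort(values, kind="stable")
    v = values[order]
    s1 = np.concatenate([[0.0], np.cumsum(v)])
    s2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def sse(i: int, j: int) -> float:  # half-open [i, j)
        m = j - i
        tot, tot2 = s1[j] - s1[i], s2[j] - s2[i]
        return tot2 - tot * tot / m

    cost = np.full((k + 1, n + 1), np.inf)
    arg = np.zeros((k + 1, n + 1), dtype=np.int64)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, best_i = np.inf, c - 1
            for i in range(c - 1, j):
                val = cost[c - 1, i] + sse(i, j)
                if val < best:
                    best, best_i = val, i
            cost[c, j], arg[c, j] = best, best_i
    bounds = [n]
    for c in range(k, 0, -1):
        bounds.append(int(arg[c, bounds[-1]]))
    bounds = bounds[::-1]  # k+1 split points, ascending

    labels_sorted = np.empty(n, dtype=np.int64)
    centroids = np.empty(k)
    for c in range(k):
        i, j = bounds[c], bounds[c + 1]
        labels_sorted[i:j] = c
        centroids[c] = v[i:j].mean() if j > i else np.nan
    labels = np.empty(n, dtype=np.int64)
    labels[order] = labels_sorted
    return labels, centroids


def order_instances(boxes, n_rows: int = 3, seed: int = 0) -> OrderedLayout:
    """Assign the stable row-major label order to a set of boxes.

    1-D K-means with ``k = n_rows`` on the centre vertical coordinate ``cy``
    groups plants into rows; rows are ordered by ascending mean ``cy`` (top
    first) and boxes within a row by ascending ``cx``, ties broken by ``cy``
    then input index.  Invariant to permutations of the input.  Fewer boxes
    than rows, or an empty cluster, yields ``skip_reason="degenerate_rows"``.
    """
    boxes = [as_box(b) for b in boxes]
    if len(boxes) < n_rows:
        return OrderedLayout(boxes=boxes, row_of=[], skip_reason="degenerate_rows")
    centers = [Center.of(b) for b in boxes]
    labels, _ = kmeans_1d([c.cy for c in centers], n_rows, seed=seed)
    if len(set(labels.tolist())) < n_rows:
        return OrderedLayout(boxes=boxes, row_of=[], skip_reason="degenerate_rows")
    order = sorted(
        range(len(boxes)),
        key=lambda i: (labels[i], centers[i].cx, centers[i].cy, i),
    )
    return OrderedLayout(
        boxes=[boxes[i] for i in order],
        row_of=[int(labels[i]) for i in order],
        skip_reason=None,
    )
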