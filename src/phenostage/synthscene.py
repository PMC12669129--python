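"""Procedural top-view bed scenes with exact ground truth.

Renders beds of rosette plants (decussate phyllotaxy: opposite leaf pairs,
successive pairs rotated ~90 deg, shrinking toward a visible shoot apex) in a
fixed pot layout around a central humidifier disk, under multiplicative LED
colour casts and additive sensor noise.  Every scene carries a
:class:`SceneTruth` with tight per-plant bounding boxes, effective leaf-pair
labels, row membership and reading order, plus an anomaly tag covering the
five frame-level failure modes seen in real chamber corpora: multiple
seedlings in one pot, dark-period frames, plants out of frame, empty
(non-germinated) pots, and leaf removal.

Realism is not the goal; separability of green foliage from background and
exact, reproducible ground truth are.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image

__all__ = [
    "InvalidSpecError",
    "PlantSpec",
    "SceneSpec",
    "SceneTruth",
    "ANOMALIES",
    "effective_pairs",
    "render_plant",
    "render_scene",
    "random_scene",
    "make_corpus",
    "default_layout",
]

ANOMALIES = ("none", "multi_seedling", "dark_frame", "out_of_frame", "empty_pot", "leaf_removed")

#: mean-luminance ceiling (uint8 scale) enforced on dark-period frames
DARK_LUMINANCE_CAP = 8.0

_BACKGROUND = np.array([52, 38, 30], dtype=np.float64)  # soil-like brown
_HUMIDIFIER = np.array([150, 150, 155], dtype=np.float64)
_POT_RIM = np.array([70, 55, 45], dtype=np.float64)
_LEAF_BASE = np.array([58, 148, 44], dtype=np.float64)
_APEX_COLOR = np.array([150, 235, 120], dtype=np.float64)  # bright young tissue


class InvalidSpecError(ValueError):
    """Raised for scene or plant specifications that violate their contract."""


@dataclass(frozen=True)
class PlantSpec:
    """One rosette: position, developmental state and leaf bookkeeping.

    ``missing_leaves`` holds ``(pair_index, side)`` marks with ``side`` in
    ``{"left", "right"}``; a pair with both sides marked is absent from the
    effective leaf-pair label.  Pair 0 is the oldest (largest) pair; sizes
    strictly decrease toward the apex so the apex disk stays visible.
    """

    center_xy: tuple[float, float]
    n_pairs: int
    base_angle: float = 0.0
    leaf_length_px: float = 40.0
    missing_leaves: frozenset[tuple[int, str]] = frozenset()
    visible: bool = True

    def __post_init__(self) -> None:
        if self.n_pairs < 0:
            raise InvalidSpecError(f"n_pairs must be >= 0, got {self.n_pairs}")
        if self.leaf_length_px <= 0:
            raise InvalidSpecError(f"leaf_length_px must be > 0, got {self.leaf_length_px}")
        for pair_idx, side in self.missing_leaves:
            if not (0 <= pair_idx < self.n_pairs):
                raise InvalidSpecError(f"missing-leaf pair index {pair_idx} out of range")
            if side not in ("left", "right"):
                raise InvalidSpecError(f"missing-leaf side must be left/right, got {side!r}")


@dataclass(frozen=True)
class SceneSpec:
    """A fully materialised bed: layout, plants and imaging conditions."""

    image_wh: tuple[int, int] = (820, 616)
    layout: tuple[tuple[float, float], ...] = ()
    layout_rows: tuple[int, ...] = ()
    plants: tuple[PlantSpec, ...] = ()
    plant_anchor: tuple[int, ...] = ()  # anchor index feeding each plant
    jitter_px: float = 10.0
    tint_rgb: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd: float = 3.0
    anomaly: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layout) < 1:
            raise InvalidSpecError("layout needs at least one anchor")
        if self.anomaly not in ANOMALIES:
            raise InvalidSpecError(f"unknown anomaly {self.anomaly!r}")
        if len(self.plants) != len(self.plant_anchor):
            raise InvalidSpecError("plants and plant_anchor must be parallel")


@dataclass
class SceneTruth:
    """Ground truth for one rendered scene.

    ``boxes`` are tight ``(x1, y1, x2, y2)`` floats in unclipped scene
    coordinates (an out-of-frame plant's box extends beyond the canvas);
    ``pairs`` are effective leaf-pair labels; ``row_of``/``order`` give the
    true row index (0 = top) and row-major reading-order rank per plant.
    """

    boxes: list[tuple[float, float, float, float]]
    pairs: list[int]
    anomaly: str
    row_of: list[int]
    order: list[int]

    def __post_init__(self) -> None:
        if not (len(self.boxes) == len(self.pairs) == len(self.row_of) == len(self.order)):
            raise InvalidSpecError("SceneTruth fields must have equal length")


def effective_pairs(n_pairs: int, missing_leaves) -> int:
    """Leaf-pair label after accounting for removed leaves.

    A pair with a single missing leaf is still counted as intact; only pairs
    with BOTH leaves absent reduce the count by one.
    """
    if n_pairs < 0:
        raise InvalidSpecError("n_pairs must be >= 0")
    missing = set(missing_leaves)
    for pair_idx, _ in missing:
        if pair_idx >= n_pairs:
            raise InvalidSpecError(f"missing-leaf pair index {pair_idx} >= n_pairs {n_pairs}")
    gone = sum(
        1
        for k in range(n_pairs)
        if (k, "left") in missing and (k, "right") in missing
    )
    return n_pairs - gone


# ---------------------------------------------------------------------------
# low-level raster helpers (operate on float64 HxWx3 canvases)
# ---------------------------------------------------------------------------

def _fill_ellipse(canvas, owner, idx, cx, cy, a, b, angle, color):
    """Fill a rotated ellipse; returns painted (row, col) index arrays."""
    h, w = canvas.shape[:2]
    ext = max(a, b) + 1.0
    r0, r1 = int(math.floor(cy - ext)), int(math.ceil(cy + ext)) + 1
    c0, c1 = int(math.floor(cx - ext)), int(math.ceil(cx + ext)) + 1
    r0c, r1c = max(r0, 0), min(r1, h)
    c0c, c1c = max(c0, 0), min(c1, w)
    if r0c >= r1c or c0c >= c1c:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    yy, xx = np.mgrid[r0c:r1c, c0c:c1c]
    dx, dy = xx - cx, yy - cy
    ca, sa = math.cos(angle), math.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    rows, cols = yy[inside], xx[inside]
    canvas[rows, cols] = color
    if owner is not None:
        owner[rows, cols] = idx
    return rows, cols


def _fill_disk(canvas, owner, idx, cx, cy, radius, color):
    return _fill_ellipse(canvas, owner, idx, cx, cy, radius, radius, 0.0, color)


def _plant_geometry(spec: PlantSpec):
    """Per-leaf placement: (pair_idx, side, angle, length, width, offset)."""
    apex_r = max(3.0, 0.09 * spec.leaf_length_px)
    # leaf inner tips overlap the apex disk by a pixel so the rosette is one
    # connected foliage region; the apex is drawn last and stays visible
    gap = apex_r - 1.0
    out = []
    for k in range(spec.n_pairs):
        length = spec.leaf_length_px * (0.88 ** k)
        width = 0.45 * length
        # decussate phyllotaxy is only approximately 90 deg in real rosettes;
        # the small extra divergence keeps every pair's tips visible from above
        theta = spec.base_angle + k * (math.pi / 2.0 + 0.13)
        for side, ang in (("left", theta), ("right", theta + math.pi)):
            if (k, side) in spec.missing_leaves:
                continue
            out.append((k, side, ang, length, width, gap))
    return apex_r, out


def plant_extent_radius(spec: PlantSpec) -> float:
    """Analytic outer radius of the rosette (apex gap + oldest leaf length)."""
    apex_r = max(3.0, 0.09 * spec.leaf_length_px)
    if spec.n_pairs == 0:
        return apex_r
    return apex_r - 1.0 + spec.leaf_length_px


def render_plant(spec: PlantSpec, canvas: np.ndarray, rng=None, owner=None, idx=0):
    """Composite one rosette onto ``canvas`` (HxWx3 float or uint8).

    Leaves are filled ellipses with slight per-leaf hue jitter; the apex is a
    small bright-green disk drawn last so it is never overdrawn by the
    plant's own leaves.  Leaves present in ``spec.missing_leaves`` are not
    drawn.  Returns ``(canvas, box)`` with ``box`` the tight axis-aligned
    ``(x1, y1, x2, y2)`` of all drawn pixels (half-open, so ``x2 = max_col+1``)
    or ``None`` when the plant lies entirely off-canvas.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    was_uint8 = canvas.dtype == np.uint8
    work = canvas.astype(np.float64) if was_uint8 else canvas
    cx, cy = spec.center_xy
    apex_r, leaves = _plant_geometry(spec)
    all_rows, all_cols = [], []
    for _k, _side, ang, length, width, gap in leaves:
        d = gap + length / 2.0
        lx, ly = cx + d * math.cos(ang), cy + d * math.sin(ang)
        color = np.clip(_LEAF_BASE + rng.uniform(-1, 1, 3) * (10.0, 16.0, 8.0), 0, 255)
        rows, cols = _fill_ellipse(work, owner, idx, lx, ly, length / 2.0, width / 2.0, ang, color)
        all_rows.append(rows)
        all_cols.append(cols)
    rows, cols = _fill_disk(work, owner, idx, cx, cy, apex_r, _APEX_COLOR)
    all_rows.append(rows)
    all_cols.append(cols)
    rows = np.concatenate(all_rows)
    cols = np.concatenate(all_cols)
    if was_uint8:
        np.copyto(canvas, np.clip(work, 0, 255).astype(np.uint8))
    box = None
    if rows.size:
        box = (float(cols.min()), float(rows.min()), float(cols.max() + 1), float(rows.max() + 1))
    return canvas, box


def default_layout(image_wh: tuple[int, int] = (820, 616)):
    """Eight pot anchors in a 3-2-3 grid around the central humidifier.

    Returns ``(anchors, rows, humidifier_center, humidifier_radius)``; rows
    are 0 = top, 1 = middle, 2 = bottom.
    """
    w, h = image_wh
    xs_outer = (0.17 * w, 0.50 * w, 0.83 * w)
    xs_mid = (0.21 * w, 0.79 * w)
    ys = (0.18 * h, 0.50 * h, 0.82 * h)
    anchors = [(x, ys[0]) for x in xs_outer]
    anchors += [(x, ys[1]) for x in xs_mid]
    anchors += [(x, ys[2]) for x in xs_outer]
    rows = (0, 0, 0, 1, 1, 2, 2, 2)
    return tuple(anchors), rows, (0.5 * w, 0.5 * h), 0.095 * w


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------

def random_scene(
    seed: int,
    anomaly: str = "none",
    pair_range: tuple[int, int] = (1, 7),
    image_wh: tuple[int, int] = (820, 616),
    jitter_px: float = 10.0,
    noise_sd: float = 3.0,
) -> SceneSpec:
    """Sample a concrete :class:`SceneSpec` for one bed.

    Leaf length grows with the pair count (older plants are larger), the LED
    tint is drawn from white-, red- and blue-shifted casts, and each plant is
    jittered uniformly around its pot anchor.  Anomaly frames are built from
    the same clean draw so only the anomaly differs.
    """
    rng = np.random.default_rng(seed)
    anchors, rows, _, _ = default_layout(image_wh)
    tints = [(1.0, 1.0, 1.0), (1.1, 0.75, 0.7), (0.75, 0.8, 1.1), (1.0, 0.9, 1.05)]
    tint = tints[int(rng.integers(len(tints)))]

    lo, hi = pair_range
    plants: list[PlantSpec] = []
    anchor_of: list[int] = []
    for i, (ax, ay) in enumerate(anchors):
        n = int(rng.integers(lo, hi + 1))
        cx = ax + rng.uniform(-jitter_px, jitter_px)
        cy = ay + rng.uniform(-jitter_px, jitter_px)
        plants.append(
            PlantSpec(
                center_xy=(cx, cy),
                n_pairs=n,
                base_angle=float(rng.uniform(0, 2 * math.pi)),
                leaf_length_px=float(22.0 + 4.0 * n + rng.uniform(-2, 2)),
            )
        )
        anchor_of.append(i)

    if anomaly == "empty_pot":
        drop = int(rng.integers(len(plants)))
        plants.pop(drop)
        anchor_of.pop(drop)
    elif anomaly == "leaf_removed":
        victim = int(rng.integers(len(plants)))
        p = plants[victim]
        if p.n_pairs >= 1:
            k = int(rng.integers(p.n_pairs))
            # one fully-removed pair plus one singly-missing leaf elsewhere
            missing = {(k, "left"), (k, "right")}
            if p.n_pairs >= 2:
                k2 = (k + 1) % p.n_pairs
                missing.add((k2, "left"))
            plants[victim] = replace(p, missing_leaves=frozenset(missing))
    elif anomaly == "multi_seedling":
        host = int(rng.integers(len(plants)))
        p = plants[host]
        off = rng.uniform(8, 14)
        ang = rng.uniform(0, 2 * math.pi)
        twin = PlantSpec(
            center_xy=(p.center_xy[0] + off * math.cos(ang), p.center_xy[1] + off * math.sin(ang)),
            n_pairs=max(1, p.n_pairs - 1),
            base_angle=float(rng.uniform(0, 2 * math.pi)),
            leaf_length_px=max(10.0, p.leaf_length_px * 0.8),
        )
        plants.insert(host + 1, twin)
        anchor_of.insert(host + 1, anchor_of[host])
    elif anomaly == "out_of_frame":
        w, h = image_wh
        victim = int(np.argmin([p.center_xy[0] for p in plants]))
        p = plants[victim]
        # push the rosette so well over half of it (apex included) leaves the frame
        plants[victim] = replace(p, center_xy=(-0.35 * plant_extent_radius(p), p.center_xy[1]), visible=False)

    return SceneSpec(
        image_wh=image_wh,
        layout=anchors,
        layout_rows=rows,
        plants=tuple(plants),
        plant_anchor=tuple(anchor_of),
        jitter_px=jitter_px,
        tint_rgb=tint,
        noise_sd=noise_sd,
        anomaly=anomaly,
        seed=seed,
    )


def _reading_order(spec: SceneSpec) -> tuple[list[int], list[int]]:
    """True row per plant and row-major (top L->R, middle, bottom) rank."""
    rows = [spec.layout_rows[a] if spec.layout_rows else 0 for a in spec.plant_anchor]
    keys = sorted(
        range(len(spec.plants)),
        key=lambda i: (rows[i], spec.plants[i].center_xy[0], spec.plants[i].center_xy[1], i),
    )
    order = [0] * len(spec.plants)
    for rank, i in enumerate(keys):
        order[i] = rank
    return rows, order


def render_scene(spec: SceneSpec, return_owner: bool = False):
    """Render a bed image and its ground truth.

    Deterministic for a fixed ``spec.seed``: two calls return bit-identical
    uint8 rasters and equal :class:`SceneTruth`.  Plants are drawn on a
    padded canvas so tight truth boxes keep their unclipped coordinates even
    for out-of-frame plants.  ``anomaly="dark_frame"`` rescales the frame to
    a mean luminance at or below ``DARK_LUMINANCE_CAP`` and empties the truth
    boxes (nothing in a dark frame is usable ground truth).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5CE7E]))
    w, h = spec.image_wh
    pad = int(math.ceil(max((plant_extent_radius(p) for p in spec.plants), default=0.0) + 4))
    canvas = np.empty((h + 2 * pad, w + 2 * pad, 3), dtype=np.float64)
    canvas[:] = _BACKGROUND + rng.uniform(-4, 4, size=(h + 2 * pad, w + 2 * pad, 1))
    owner = np.full(canvas.shape[:2], -1, dtype=np.int32)

    _, _, hum_c, hum_r = default_layout(spec.image_wh)
    _fill_disk(canvas, None, 0, hum_c[0] + pad, hum_c[1] + pad, hum_r, _HUMIDIFIER)
    for ax, ay in spec.layout:
        _fill_disk(canvas, None, 0, ax + pad, ay + pad, 0.085 * w / 2 + 18, _POT_RIM)

    boxes = []
    for i, plant in enumerate(spec.plants):
        shifted = replace(plant, center_xy=(plant.center_xy[0] + pad, plant.center_xy[1] + pad))
        _, box = render_plant(shifted, canvas, rng=rng, owner=owner, idx=i)
        if box is None:
            r = plant_extent_radius(plant)
            cx, cy = plant.center_xy
            boxes.append((cx - r, cy - r, cx + r, cy + r))
        else:
            boxes.append((box[0] - pad, box[1] - pad, box[2] - pad, box[3] - pad))

    canvas = canvas[pad : pad + h, pad : pad + w]
    owner = owner[pad : pad + h, pad : pad + w]

    canvas = canvas * np.asarray(spec.tint_rgb, dtype=np.float64)
    if spec.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    canvas = np.clip(canvas, 0, 255)

    rows, order = _reading_order(spec)
    pairs = [effective_pairs(p.n_pairs, p.missing_leaves) for p in spec.plants]
    if spec.anomaly == "dark_frame":
        lum = canvas.mean()
        if lum > 0:
            canvas = canvas * min(1.0, (DARK_LUMINANCE_CAP - 3.0) / lum)
        truth = SceneTruth(boxes=[], pairs=[], anomaly="dark_frame", row_of=[], order=[])
    else:
        truth = SceneTruth(boxes=boxes, pairs=pairs, anomaly=spec.anomaly, row_of=rows, order=order)

    image = np.clip(canvas, 0, 255).astype(np.uint8)
    if return_owner:
        return image, truth, owner
    return image, truth


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------

def make_corpus(
    n_scenes: int,
    out_dir,
    pair_range: tuple[int, int] = (1, 7),
    anomaly_rates: dict | None = None,
    seed: int = 0,
    image_wh: tuple[int, int] = (820, 616),
):
    """Write ``n_scenes`` PNG bed images plus a ground-truth CSV.

    Anomalies are injected by deterministic assignment, not sampling: scene
    indices are shuffled once with ``seed`` and the first ``floor(rate * n)``
    of each category (in a fixed category order) receive that anomaly, so the
    corpus composition is exactly reproducible.  Returns a list of
    ``(image_path, SceneTruth)`` in scene order.
    """
    import pandas as pd
    from pathlib import Path

    rates = dict(anomaly_rates or {})
    unknown = set(rates) - set(ANOMALIES[1:])
    if unknown:
        raise InvalidSpecError(f"unknown anomaly categories: {sorted(unknown)}")
    if sum(rates.values()) > 1.0 + 1e-9:
        raise InvalidSpecError("anomaly rates must sum to <= 1")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0B905]))
    shuffled = list(rng.permutation(n_scenes))
    assignment = {i: "none" for i in range(n_scenes)}
    cursor = 0
    for cat in ANOMALIES[1:]:
        k = int(math.floor(rates.get(cat, 0.0) * n_scenes))
        for i in shuffled[cursor : cursor + k]:
            assignment[int(i)] = cat
        cursor += k

    records = []
    out: list = []
    for sid in range(n_scenes):
        scene_seed = int((seed * 1_000_003 + sid) % (2**31 - 1))
        spec = random_scene(scene_seed, anomaly=assignment[sid], pair_range=pair_range, image_wh=image_wh)
        image, truth = render_scene(spec)
        path = out_dir / f"scene_{sid:04d}.png"
        Image.fromarray(image).save(path)
        out.append((path, truth))
        if not truth.boxes:
            records.append(
                dict(scene_id=sid, plant_idx=-1, x1=np.nan, y1=np.nan, x2=np.nan, y2=np.nan,
                     pairs=-1, row=-1, order=-1, anomaly=truth.anomaly)
            )
        for j, (box, pr) in enumerate(zip(truth.boxes, truth.pairs)):
            records.append(
                dict(scene_id=sid, plant_idx=j, x1=box[0], y1=box[1], x2=box[2], y2=box[3],
                     pairs=pr, row=truth.row_of[j], order=truth.order[j], anomaly=truth.anomaly)
            )
    pd.DataFrame.from_records(records).to_csv(out_dir / "truth.csv", index=False)
    return out


def read_truth_csv(path):
    """Load a ``make_corpus`` ground-truth CSV back into SceneTruth objects."""
    import pandas as pd

    df = pd.read_csv(path)
    truths: dict[int, SceneTruth] = {}
    for sid, grp in df.groupby("scene_id"):
        grp = grp.sort_values("plant_idx")
        anomaly = str(grp["anomaly"].iloc[0])
        real = grp[grp["plant_idx"] >= 0]
        truths[int(sid)] = SceneTruth(
            boxes=[(r.x1, r.y1, r.x2, r.y2) for r in real.itertuples()],
            pairs=[int(p) for p in real["pairs"]],
            anomaly=anomaly,
            row_of=[int(r) for r in real["row"]],
            order=[int(o) for o in real["order"]],
        )
    return truths
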