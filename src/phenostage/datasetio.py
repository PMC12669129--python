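"""Dataset construction: frame exclusions, instance cropping, manifests,
splits and count tables.

The unit of training data is a cropped plant instance paired with its
leaf-pair label.  Frames with unusable ground truth (multiple seedlings per
pot, dark-period frames, plants mostly out of frame or with hidden apex,
non-germinated pots) are excluded up front; frames with leaf removal are
kept, their labels already adjusted by the effective-pair rule.  Manifests
are plain CSV tables; splits are seeded shuffles sliced by the
floor-floor-remainder convention.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .boxflow import OrderedLayout
from .detect import as_box
from .synthscene import SceneTruth, DARK_LUMINANCE_CAP

log = logging.getLogger(__name__)

__all__ = [
    "Manifest",
    "SplitSpec",
    "exclude_frames",
    "crop_instances",
    "split_dataset",
    "split_sizes",
    "tally",
]

MANIFEST_COLUMNS = ["crop_path", "pairs", "scene_id", "plant_idx", "chamber_id", "split"]


@dataclass
class Manifest:
    """Table of crop/label samples with provenance.

    ``samples`` columns: crop_path, pairs, scene_id, plant_idx, chamber_id,
    split.  ``provenance`` records the generator seed and a pipeline config
    hash so a manifest can be traced back to the run that built it.
    """

    samples: pd.DataFrame
    provenance: dict | None = None

    def __post_init__(self) -> None:
        df = self.samples
        for col in ("crop_path", "pairs", "scene_id", "plant_idx"):
            if col not in df.columns:
                raise ValueError(f"manifest missing column {col!r}")
        dup = df.duplicated(subset=["scene_id", "plant_idx"])
        if dup.any():
            raise ValueError("duplicate (scene_id, plant_idx) rows in manifest")

    def __len__(self) -> int:
        return len(self.samples)

    def write(self, path) -> None:
        path = Path(path)
        df = self.samples.copy()
        for col in MANIFEST_COLUMNS:
            if col not in df.columns:
                df[col] = ""
        df[MANIFEST_COLUMNS].to_csv(path, index=False)
        if self.provenance is not None:
            path.with_suffix(".provenance.json").write_text(json.dumps(self.provenance, indent=2))

    @classmethod
    def read(cls, path) -> "Manifest":
        path = Path(path)
        df = pd.read_csv(path, keep_default_na=False)
        df["pairs"] = df["pairs"].astype(int)
        prov_path = path.with_suffix(".provenance.json")
        prov = json.loads(prov_path.read_text()) if prov_path.exists() else None
        return cls(samples=df, provenance=prov)


@dataclass(frozen=True)
class SplitSpec:
    """Train/val/test fractions plus seed; floor-floor-remainder sizing."""

    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if any(r < 0 for r in self.ratios):
            raise ValueError("split ratios must be non-negative")


def split_sizes(n: int, ratios=(0.7, 0.2, 0.1)) -> tuple[int, int, int]:
    """Floor-floor-remainder split sizes: |train| = floor(n*r_t), |val| =
    floor(n*r_v), |test| = the rest."""
    n_train = int(np.floor(n * ratios[0]))
    n_val = int(np.floor(n * ratios[1]))
    return n_train, n_val, n - n_train - n_val


def split_dataset(manifest: Manifest, spec: SplitSpec = SplitSpec()):
    """Seeded shuffle + contiguous slicing into (train, val, test) manifests.

    Deterministic for a fixed seed; the three parts are disjoint and their
    union is the input.  Splitting is instance-level: crops of the same
    scene may land in different parts.
    """
    n = len(manifest)
    if n == 0:
        raise ValueError("cannot split an empty manifest")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_train, n_val, _ = split_sizes(n, spec.ratios)
    idx = {
        "train": perm[:n_train],
        "val": perm[n_train : n_train + n_val],
        "test": perm[n_train + n_val :],
    }
    out = []
    for name in ("train", "val", "test"):
        df = manifest.samples.iloc[np.sort(idx[name])].copy()
        df["split"] = name
        out.append(Manifest(samples=df.reset_index(drop=True), provenance=manifest.provenance))
    return tuple(out)


# ---------------------------------------------------------------------------
# frame-level exclusions
# ---------------------------------------------------------------------------

def _out_of_frame(truth: SceneTruth, image_wh) -> bool:
    """True when a truth box extends more than half outside the frame or the
    plant's apex (box centre) is off-frame."""
    w, h = image_wh
    for x1, y1, x2, y2 in truth.boxes:
        area = (x2 - x1) * (y2 - y1)
        ix = min(x2, w) - max(x1, 0.0)
        iy = min(y2, h) - max(y1, 0.0)
        inside = max(ix, 0.0) * max(iy, 0.0)
        if inside < 0.5 * area:
            return True
        cx, cy = (x1 + x2) / 2.0, (y1 + y2) / 2.0
        if not (0 <= cx < w and 0 <= cy < h):
            return True
    return False


def exclude_frames(scenes, expected_count: int = 8, image_wh=(820, 616),
                   dark_cap: float = DARK_LUMINANCE_CAP + 2.0):
    """Apply frame-level exclusion rules; returns (kept, exclusion_log).

    ``scenes`` is a sequence of ``(scene_id, image_or_path, SceneTruth)``.
    Dropped: multi-seedling frames, dark frames (mean luminance below
    ``dark_cap`` — tested on pixels, so untagged dark frames are still
    caught), out-of-frame plants, and frames with fewer than the expected
    plant count (empty pots).  Frames with leaf removal are KEPT; their
    labels were already adjusted when counting pairs.  The log is a list of
    ``(scene_id, reason)`` and the exclusion is reproducible from it.
    """
    kept, excluded = [], []
    for scene_id, image, truth in scenes:
        reason = None
        img = image
        if isinstance(image, (str, Path)):
            img = np.asarray(Image.open(image))
        if truth.anomaly == "multi_seedling" or len(truth.boxes) > expected_count:
            reason = "multi_seedling"
        elif np.asarray(img, dtype=np.float64).mean() < dark_cap or truth.anomaly == "dark_frame":
            reason = "dark_frame"
        elif _out_of_frame(truth, image_wh):
            reason = "out_of_frame"
        elif len(truth.boxes) < expected_count:
            reason = "empty_pot"
        if reason is None:
            kept.append((scene_id, image, truth))
        else:
            excluded.append((scene_id, reason))
    return kept, excluded


def write_exclusion_log(excluded, path) -> None:
    pd.DataFrame(excluded, columns=["scene_id", "reason"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cropping
# ---------------------------------------------------------------------------

def crop_box(image: np.ndarray, box, resize_side: int | None = None) -> np.ndarray:
    """Extract one crop with the half-open integer convention, clipping to
    the frame (with a warning) when the box overhangs it."""
    b = as_box(box)
    h, w = image.shape[:2]
    c0, c1 = int(np.floor(b.x1)), int(np.ceil(b.x2))
    r0, r1 = int(np.floor(b.y1)), int(np.ceil(b.y2))
    if c0 < 0 or r0 < 0 or c1 > w or r1 > h:
        log.warning("box %s exceeds %dx%d frame; clipping", b.as_tuple(), w, h)
        c0, r0 = max(c0, 0), max(r0, 0)
        c1, r1 = min(c1, w), min(r1, h)
    crop = image[r0:r1, c0:c1]
    if resize_side is not None and crop.size:
        crop = np.asarray(
            Image.fromarray(np.ascontiguousarray(crop)).resize(
                (resize_side, resize_side), Image.BILINEAR
            )
        )
    return crop


def crop_instances(image: np.ndarray, layout: OrderedLayout, resize_side: int | None = None):
    """One crop per box of a non-skipped layout, in label order."""
    if layout.skipped:
        raise ValueError(f"cannot crop a skipped frame ({layout.skip_reason})")
    return [crop_box(image, b, resize_side=resize_side) for b in layout.boxes]


def build_manifest(rows, provenance: dict | None = None) -> Manifest:
    """Assemble a Manifest from an iterable of sample dicts."""
    df = pd.DataFrame(rows)
    if "chamber_id" not in df.columns:
        df["chamber_id"] = ""
    if "split" not in df.columns:
        df["split"] = ""
    return Manifest(samples=df[MANIFEST_COLUMNS], provenance=provenance)


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable config, for provenance."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def tally(values, group_key=None):
    """Per-group counts and grand total.

    ``values`` may be a Manifest, a DataFrame, a mapping of group -> count,
    or a plain sequence of counts (indexed 1..n).  Returns ``(counts,
    total)`` with ``counts`` a pandas Series indexed by group.
    """
    if isinstance(values, Manifest):
        values = values.samples
    if isinstance(values, pd.DataFrame):
        if group_key is None:
            raise ValueError("group_key required for table input")
        counts = values.groupby(group_key).size()
    elif isinstance(values, dict):
        counts = pd.Series(values, dtype="int64")
    else:
        seq = list(values)
        counts = pd.Series(seq, index=range(1, len(seq) + 1), dtype="int64")
    return counts, int(counts.sum())
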