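"""Glue: turn a rendered corpus into cropped train/val/test manifests.

Reads the PNGs and ground-truth CSV of a generated corpus, applies the
frame-level exclusion rules, detects (or replays) boxes, orders instances
into the stable row-major labelling, crops each instance, pairs it with the
leaf-pair label of the ground-truth plant at the same reading-order rank,
and splits the resulting manifest 70:20:10.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from PIL import Image

from . import boxflow, detect
from .datasetio import (
    Manifest,
    SplitSpec,
    build_manifest,
    config_hash,
    crop_instances,
    exclude_frames,
    split_dataset,
    write_exclusion_log,
)
from .synthscene import read_truth_csv

log = logging.getLogger(__name__)

__all__ = ["build_crop_dataset", "crop_corpus"]


def crop_corpus(
    corpus_dir,
    out_dir,
    detector: str = "replay",
    conf_threshold: float = 0.0,
    nested_tolerance_px: float = 10.0,
    expected_count: int = 8,
    n_rows: int = 3,
    resize_side: int = 128,
    seed: int = 0,
) -> Manifest:
    """Crop every usable frame of a corpus into labelled instance PNGs.

    With ``detector="replay"`` the ground-truth boxes stand in for a trained
    detector (exact labels, no detection error); ``detector="reference"``
    runs the classical foliage detector instead, and frames where it does
    not find exactly the expected count are skipped.
    """
    corpus_dir = Path(corpus_dir)
    out_dir = Path(out_dir)
    crops_dir = out_dir / "crops"
    crops_dir.mkdir(parents=True, exist_ok=True)

    truths = read_truth_csv(corpus_dir / "truth.csv")
    scenes = []
    for sid in sorted(truths):
        path = corpus_dir / f"scene_{sid:04d}.png"
        if path.exists():
            scenes.append((sid, path, truths[sid]))
    kept, excluded = exclude_frames(scenes, expected_count=expected_count)
    write_exclusion_log(excluded, out_dir / "exclusions.csv")

    rows = []
    for sid, path, truth in kept:
        image = np.asarray(Image.open(path).convert("RGB"))
        if detector == "replay":
            boxes = [detect.Box(*b, conf=1.0) for b in truth.boxes]
        else:
            boxes = detect.reference_detect(image)
            boxes = boxflow.filter_confidence(boxes, conf_threshold)
            boxes = boxflow.remove_nested(boxes, nested_tolerance_px)
        layout = boxflow.enforce_count(boxes, expected_count)
        if not layout.skipped:
            layout = boxflow.order_instances(layout.boxes, n_rows=n_rows, seed=seed)
        if layout.skipped:
            log.info("scene %d skipped: %s", sid, layout.skip_reason)
            continue
        # label for rank r = pairs of the ground-truth plant whose order == r
        pairs_by_rank = {truth.order[i]: truth.pairs[i] for i in range(len(truth.pairs))}
        crops = crop_instances(image, layout, resize_side=resize_side)
        for rank, crop in enumerate(crops):
            crop_path = crops_dir / f"scene_{sid:04d}_plant_{rank}.png"
            Image.fromarray(crop).save(crop_path)
            rows.append(dict(crop_path=str(crop_path), pairs=int(pairs_by_rank[rank]),
                             scene_id=sid, plant_idx=rank))
    prov = dict(
        corpus=str(corpus_dir), seed=seed,
        config=config_hash(dict(detector=detector, conf_threshold=conf_threshold,
                                nested_tolerance_px=nested_tolerance_px,
                                expected_count=expected_count, n_rows=n_rows,
                                resize_side=resize_side)),
    )
    return build_manifest(rows, provenance=prov)


def build_crop_dataset(corpus_dir, out_dir, seed: int = 0, resize_side: int = 128,
                       detector: str = "replay", ratios=(0.7, 0.2, 0.1)):
    """Crop a corpus and split it into (train, val, test) manifests on disk."""
    out_dir = Path(out_dir)
    manifest = crop_corpus(corpus_dir, out_dir, detector=detector,
                           resize_side=resize_side, seed=seed)
    if len(manifest) == 0:
        raise ValueError(f"no usable frames in {corpus_dir}")
    parts = split_dataset(manifest, SplitSpec(ratios=ratios, seed=seed))
    for name, part in zip(("train", "val", "test"), parts):
        part.write(out_dir / f"{name}.csv")
    return parts
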