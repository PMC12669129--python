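# Methods

`phenostage` implements an instance-level growth-stage pipeline for rosette
herbs (basil-like, decussate phyllotaxy) grown in fixed beds and imaged from
above: **detect** every plant in the frame, **order** the detections into a
stable row-major labelling, **regress** the leaf-pair count from each crop,
and **stage** the count on a BBCH-aligned three-level rule. A procedural
scene generator supplies exact ground truth for every step, so the whole
pipeline is testable at desk scale without chamber hardware.

## Staging model

The developmental state of a plant is summarised by the number of leaf
pairs `n` visible at the shoot apex. Growth levels are fixed integer
intervals of `n`:

    Level 1: n <= 2      Level 2: 3 <= n <= 4      Level 3: n >= 5

The mapping is total and monotone; boundaries are configurable
(`StageRule(boundaries=(2, 4))` is the default). Leaf removal is handled at
the counting stage, not by frame exclusion: a pair missing one leaf still
counts as intact, a pair missing both leaves reduces `n` by one
(`effective_pairs`).

## Synthetic scenes

`synthscene` renders a bed of eight rosettes in a 3–2–3 pot grid around a
central humidifier disk (820×616 px, a quarter-scale canvas with the aspect
ratio of common 8 MP chamber cameras). Each plant is a stack of elliptical
leaves: pair `k` has length `L·0.88^k` (strictly decreasing toward the
apex) and is rotated `k·(90° + 7.4°)` from the oldest pair. The 7.4°
divergence beyond exact decussation matters: with a perfect 90° rotation
all pairs superimpose onto two axes in top view and the count becomes
structurally unrecoverable from a single image, contradicting the
observable the whole pipeline is built on (pairs countable at the apex).
Real rosettes show comparable phyllotactic variation. The apex is a small
bright disk drawn last, so it is never covered by the plant's own leaves;
pot spacing guarantees neighbours cannot reach it in clean scenes.

Imaging conditions emulated: multiplicative LED colour casts (white-,
red- and blue-shifted tints), additive Gaussian sensor noise (σ = 3 on the
0–255 scale), uniform ±10 px pot jitter, and leaf size increasing with
pair count (`L = 22 + 4n ± 2` px) as in real growth. Five frame-level
anomaly types are injected by deterministic assignment (first ⌊rate·n⌋
scenes per category after a seeded shuffle, so corpus composition is exactly
reproducible): multiple seedlings per pot, dark-period frames (mean
luminance rescaled below 8/255), plants mostly out of frame, empty pots,
and leaf removal. Ground truth carries tight per-plant boxes in *unclipped*
coordinates (an out-of-frame plant's box extends beyond the canvas), the
effective pair label, true row and reading-order rank, and the anomaly tag.

What the generator does **not** emulate: leaf occlusion between
neighbouring plants, perspective and lens distortion, specular highlights,
soil texture variation, and continuous growth over time. Passing the
parameter-recovery tests therefore shows that the pipeline's machinery is
correct and that the regressor can recover a countable trait under colour
casts and noise — not that the shipped weights transfer to real imagery;
on real data the detector and regressor are meant to be retrained behind
the same contracts.

## Detection and post-processing

The detector contract is a function returning axis-aligned boxes with
confidences; anything satisfying it (a neural detector via the external CSV
adapter, a replay of ground truth, or the built-in classical detector) can
drive the pipeline. The reference detector normalises each channel by its
image mean (cancelling multiplicative casts), thresholds the excess-green
index `2g − r − b > 0.45`, and converts connected components above
`min_area_px = 60` into boxes with `conf = min(1, area/150)`.

Post-processing follows the operating rules of the chamber pipeline:

1. **Confidence filter** — keep boxes with `conf` strictly above the
   operating threshold (default 0.706, taken from an F1–confidence sweep).
2. **Nested-box removal** — a box is dropped iff a kept box of at least its
   area contains it once expanded by a 10 px tolerance on all four sides;
   processed largest-first, idempotent, equal areas keep the higher
   confidence. The 10 px default is referenced to full-resolution frames;
   scaled configurations must set it explicitly.
3. **Exact-count rule** — a frame survives only if exactly the expected
   number of plants (8) remains; otherwise it is skipped and the per-stage
   box counts are logged (raw / thresholded / denested), which makes
   skip-rate accounting a query over the log.
4. **Row ordering** — K-means with `k = 3` on the box-centre vertical
   coordinate groups plants into rows; rows are ranked top→bottom and
   plants left→right within each row. Because the problem is
   one-dimensional we solve K-means *exactly* by dynamic programming over
   contiguous partitions of the sorted coordinates — deterministic,
   permutation-invariant, and free of the local optima Lloyd iterations
   exhibit on uneven (3–2–3) cluster sizes.

Measured robustness of the ordering: with pots jittered uniformly by up to
25 % of the inter-row spacing, the K-means ordering agrees with the
true-row oracle in 1000/1000 seeded trials; first disagreements appear
near 30 % and grow beyond (at ~39 % about 11 % of layouts disagree). That
boundary is a property of clustering on the vertical coordinate itself —
the globally optimal partition genuinely stops matching the physical rows
— not of the implementation. The generator's operating jitter (10 px ≈ 5 %)
sits far inside the safe region.

## Leaf-pair regression

Crops are extracted with the half-open integer convention
`[⌊x1⌋,⌈x2⌉)×[⌊y1⌋,⌈y2⌉)`, resized square, and regressed to a continuous
pair count. Regression (not classification) is used so an error of three
pairs costs more than an error of one. Training minimises the Huber
objective

    l = ½(x−y)²            if |x−y| < δ
    l = δ(|x−y| − ½δ)      otherwise

with δ = 1.0 by default (one leaf pair; the knee is continuous and
once-differentiable), under AdamW (decoupled weight decay) with early
stopping on validation loss and best-epoch weight restoration. The network
backend is a compact, fully-tested numpy implementation (3×3 convolutions
as nine shifted tensor contractions, 2×2 max-pool, dense head with
dropout); backbones: `small_conv` (four conv+pool blocks, default) and
`residual18` (conv stem + residual pairs, slower, provided for parity with
larger configurations). Dropout applies to the dense head only.

Two configuration presets:

* **chamber** — the tuned configuration for large real corpora: lr 3.67e-5,
  weight decay 4.81e-4, dropout 0.134, patience 7, LeakyReLU, colour jitter
  ±10.6/24.5/36.6/5.6 % (brightness/contrast/saturation/hue), horizontal
  flip p = 0.263, rotation ±10°, no LR schedule.
* **desk** (`desk_config()`) — for synthetic corpora of a few thousand
  crops: lr 2e-3, input side 48 px, batch 64, ≤ 60 epochs, patience 10,
  other fields unchanged. The tuned chamber learning rate is too slow to
  converge on small corpora within a sensible epoch budget; this is the one
  documented divergence between presets.

All augmentations are label-preserving (mirroring, small rotations and
photometric jitter cannot change a pair count) and seeded. Predictions are
rounded half-up and clamped to `[0, max_pairs]` before staging.

An optional hyperparameter-search harness does seeded random search with
median pruning (a trial whose validation curve falls above the median of
completed trials at the same epoch is stopped early).

## Evaluation

Detection: IoU, greedy confidence-descending one-to-one matching at an IoU
threshold (precision defined as 1 when there are no predictions, so
threshold sweeps are total), F1–confidence curves with ties broken toward
the higher threshold, and all-point interpolated AP / mAP@0.5:0.95.
Greedy matching can in principle under-match relative to the optimal
assignment; tests compare it against an exhaustive-permutation oracle and
confirm equality on non-overlapping layouts (the bed geometry).

Regression: MAE, MSE, RMSE, R² (raising an error on zero-variance targets
rather than returning NaN). Staging: accuracy, support-weighted F1, and a
row-normalised confusion matrix. Cross-validation uses seeded k-fold
instance-level partitions, holding each fold out once with an inner
85:15 train/early-stop split.

Dataset splits are instance-level (crops of one scene may land in
different parts, matching the chamber protocol) with floor-floor-remainder
sizing: |train| = ⌊N·0.7⌋, |val| = ⌊N·0.2⌋, |test| = remainder — the
convention that reproduces 9,009/2,574/1,288 from N = 12,871. A
scene-grouped split is available but off by default.

## Problem sizes used by the test suite and acceptance script

Chosen to exercise every code path on one CPU: 100-scene clean corpora for
detector evaluation, a 250-scene corpus (≈ 2,000 crops, ≈ 1,400 train)
for parameter recovery, 1,000 jittered layouts for the ordering oracle,
and k = 3 reduced cross-validation on 180 crops. Typical desk-scale
results (recomputed from scratch by `scripts/acceptance.py`): held-out
MAE ≈ 0.18, stage accuracy ≈ 0.99, reference-detector precision/recall
≈ 1.00 at IoU 0.5.

## Known limitations

* The classical reference detector is tuned to the generator's colour
  statistics; it is a stand-in for a trained detector behind the same
  contract, not a general foliage segmenter.
* Confidence semantics differ between detectors (component area vs
  network score); the operating threshold is meaningful only per detector.
* Ordering assumes a fixed number of rows; layouts with unknown row
  structure are out of scope.
* No temporal modelling: each frame is staged independently.
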