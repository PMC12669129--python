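"""Growth-level mapping and the evaluation suite.

The leaf-pair count is discretised into three growth levels by fixed
interval thresholds (default: <=2 pairs is Level 1, 3-4 pairs Level 2, >=5
pairs Level 3 — the BBCH-aligned staging used for rosette herbs).
Regression quality is reported as MAE / MSE / RMSE / R^2, staging quality as
accuracy, support-weighted F1 and a row-normalised confusion matrix, and
robustness via seeded k-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score as _sk_f1
from sklearn.model_selection import KFold

from .datasetio import Manifest

__all__ = [
    "StageRule",
    "MetricReport",
    "map_stage",
    "regression_metrics",
    "classification_metrics",
    "kfold_cv",
]


@dataclass(frozen=True)
class StageRule:
    """Ordered upper boundaries partitioning pair counts into levels.

    ``boundaries=(2, 4)`` means: pairs <= 2 -> Level 1, 3-4 -> Level 2,
    >= 5 -> Level 3.  Levels are 1-based integers; the mapping is total and
    monotone non-decreasing in the pair count.
    """

    boundaries: tuple[int, ...] = (2, 4)

    def __post_init__(self) -> None:
        if any(b >= c for b, c in zip(self.boundaries, self.boundaries[1:])):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def n_levels(self) -> int:
        return len(self.boundaries) + 1

    @property
    def labels(self) -> list[int]:
        return list(range(1, self.n_levels + 1))


DEFAULT_RULE = StageRule()


def map_stage(pairs, rule: StageRule = DEFAULT_RULE):
    """Growth level (1-based) for a pair count; vectorised over arrays."""
    arr = np.asarray(pairs)
    if np.any(arr < 0):
        raise ValueError("pair counts must be >= 0")
    # side="left": a count equal to a boundary stays in the lower level (2 -> Level 1)
    level = np.searchsorted(np.asarray(rule.boundaries), arr, side="left") + 1
    if np.isscalar(pairs) or arr.ndim == 0:
        return int(level)
    return level.astype(int)


@dataclass
class MetricReport:
    """Regression and staging metrics for one evaluation."""

    mae: float
    mse: float
    rmse: float
    r2: float
    accuracy: float
    weighted_f1: float
    confusion: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def as_dict(self) -> dict:
        return dict(mae=self.mae, mse=self.mse, rmse=self.rmse, r2=self.r2,
                    accuracy=self.accuracy, weighted_f1=self.weighted_f1)


def regression_metrics(predictions, targets) -> dict:
    """MAE, MSE, RMSE and R^2 = 1 - SS_res/SS_tot.

    Raises on constant targets (R^2 undefined with zero target variance) and
    on batches of fewer than two samples.
    """
    x = np.asarray(predictions, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need n >= 2 for R^2")
    err = x - y
    mae = float(np.abs(err).mean())
    mse = float((err**2).mean())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: targets have zero variance")
    r2 = 1.0 - float((err**2).sum()) / ss_tot
    return dict(mae=mae, mse=mse, rmse=float(np.sqrt(mse)), r2=r2)


def classification_metrics(true_levels, pred_levels, labels=None) -> dict:
    """Accuracy, support-weighted F1 and a row-normalised confusion matrix.

    Confusion rows are true levels; each realised row sums to 1.
    """
    t = np.asarray(true_levels)
    p = np.asarray(pred_levels)
    if t.shape != p.shape or t.size == 0:
        raise ValueError("need equal non-empty sequences")
    if labels is None:
        labels = sorted(set(t.tolist()) | set(p.tolist()))
    acc = float((t == p).mean())
    wf1 = float(_sk_f1(t, p, labels=labels, average="weighted", zero_division=0))
    conf = _sk_confusion(t, p, labels=labels).astype(np.float64)
    row_sums = conf.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        conf = np.where(row_sums > 0, conf / row_sums, 0.0)
    return dict(accuracy=acc, weighted_f1=wf1, confusion=conf, labels=list(labels))


def evaluate(predictions, targets, rule: StageRule = DEFAULT_RULE, max_pairs: int = 10) -> MetricReport:
    """Full report: regression metrics on raw predictions, staging metrics
    after rounding/clamping and level mapping."""
    from .leafreg import round_clamp

    reg = regression_metrics(predictions, targets)
    pred_levels = map_stage(round_clamp(predictions, max_pairs), rule)
    true_levels = map_stage(np.asarray(targets, dtype=int), rule)
    cls = classification_metrics(true_levels, pred_levels, labels=rule.labels)
    return MetricReport(confusion=cls["confusion"], accuracy=cls["accuracy"],
                        weighted_f1=cls["weighted_f1"], **reg)


def kfold_cv(
    manifest: Manifest,
    k: int = 5,
    cfg=None,
    aug=None,
    seed: int = 0,
    rule: StageRule = DEFAULT_RULE,
):
    """Seeded k-fold cross-validation of the leaf-pair regressor.

    Each fold is held out once; the remaining folds are split 85:15 into
    train/early-stopping-validation.  Returns ``(reports, summary)`` where
    ``summary`` is a DataFrame of per-metric mean and standard deviation.
    """
    from .leafreg import NO_AUGMENT, desk_config, predict_pairs, train_regressor, _load_crops

    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(manifest)
    if n < k:
        raise ValueError("manifest smaller than k")
    cfg = cfg or desk_config()
    aug = aug or NO_AUGMENT
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    reports: list[MetricReport] = []
    df = manifest.samples.reset_index(drop=True)
    for fold, (train_idx, test_idx) in enumerate(kf.split(df)):
        rng = np.random.default_rng(np.random.SeedSequence([seed, fold]))
        train_idx = rng.permutation(train_idx)
        n_val = max(1, int(0.15 * len(train_idx)))
        val_m = Manifest(df.iloc[np.sort(train_idx[:n_val])].reset_index(drop=True))
        tr_m = Manifest(df.iloc[np.sort(train_idx[n_val:])].reset_index(drop=True))
        te_m = Manifest(df.iloc[test_idx].reset_index(drop=True))
        fitted = train_regressor(tr_m, val_m, cfg, aug)
        x_test, y_test = _load_crops(te_m, cfg.input_side)
        preds = predict_pairs(fitted, x_test)
        reports.append(evaluate(preds, y_test, rule))
    table = pd.DataFrame([r.as_dict() for r in reports])
    summary = pd.DataFrame({"mean": table.mean(), "sd": table.std(ddof=1)})
    return reports, summary
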