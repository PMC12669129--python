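"""Shared fixtures: synthetic corpora and one trained regressor per session.

Everything is generated programmatically at test time; the heavyweight
artifacts (the 250-scene training corpus and the fitted model) are built
once per session and shared by the training, cross-validation and
end-to-end tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from phenostage.dataset_builder import build_crop_dataset
from phenostage.datasetio import Manifest
from phenostage.leafreg import NO_AUGMENT, desk_config, train_regressor
from phenostage.synthscene import make_corpus, read_truth_csv

CLEAN_CORPUS_SEED = 11
TRAIN_CORPUS_SEED = 23
ANOMALY_CORPUS_SEED = 5


@pytest.fixture(scope="session")
def clean_corpus(tmp_path_factory):
    """100 clean scenes for detection evaluation and end-to-end runs."""
    root = tmp_path_factory.mktemp("clean_corpus")
    scenes = make_corpus(100, root, anomaly_rates={}, seed=CLEAN_CORPUS_SEED)
    return root, scenes


@pytest.fixture(scope="session")
def anomaly_corpus(tmp_path_factory):
    """50 scenes, ten of each anomaly type (assignment-based injection)."""
    root = tmp_path_factory.mktemp("anomaly_corpus")
    rates = {k: 0.2 for k in ("multi_seedling", "dark_frame", "out_of_frame", "empty_pot", "leaf_removed")}
    scenes = make_corpus(50, root, anomaly_rates=rates, seed=ANOMALY_CORPUS_SEED)
    return root, scenes


@pytest.fixture(scope="session")
def crop_dataset(tmp_path_factory):
    """~1,500 training crops (pairs 1-7) split 70:20:10."""
    corpus = tmp_path_factory.mktemp("train_corpus")
    make_corpus(250, corpus, pair_range=(1, 7), anomaly_rates={}, seed=TRAIN_CORPUS_SEED)
    out = tmp_path_factory.mktemp("crop_dataset")
    train, val, test = build_crop_dataset(corpus, out, seed=TRAIN_CORPUS_SEED, resize_side=64)
    return train, val, test


@pytest.fixture(scope="session")
def fitted_regressor(crop_dataset):
    """The desk-scale regressor trained once for the whole session."""
    train, val, _ = crop_dataset
    cfg = desk_config(seed=1)
    return train_regressor(train, val, cfg, NO_AUGMENT)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
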