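"""Shared fixtures: the synthetic study and a model trained on it.

The trained model is expensive (200 epochs), so it is built once per
session and reused by the training-property and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from chemaae.dataset import SyntheticSpec, generate_synthetic
from chemaae.model import ModelConfig, encode, init_model
from chemaae.training import TrainConfig, fit

STUDY_SEED = 1
N_TRAIN = 500
N_HELDOUT = 100


def mean_same_fp_cosine(params, X, norm_stats, seed=7):
    """Mean cosine similarity between representations of the same fingerprint
    encoded at two concentrations drawn from the dataset's LCONC moments."""
    rng = np.random.default_rng(seed)
    draws = rng.normal(norm_stats.lconc_mean, np.sqrt(norm_stats.lconc_var), size=(len(X), 2))
    _, r1 = encode(params, X, draws[:, 0])
    _, r2 = encode(params, X, draws[:, 1])
    num = (r1 * r2).sum(axis=1)
    den = np.linalg.norm(r1, axis=1) * np.linalg.norm(r2, axis=1)
    return float((num / np.maximum(den, 1e-12)).mean())


@pytest.fixture(scope="session")
def study():
    """Synthetic study conditions: 500 training compounds from 4 prototypes
    with 5% bit flips, plus 100 held-out compounds from the same generator."""
    spec = SyntheticSpec(n_compounds=N_TRAIN + N_HELDOUT, n_prototypes=4,
                         bit_flip_rate=0.05, seed=STUDY_SEED)
    full, truth = generate_synthetic(spec)
    return {
        "spec": spec,
        "truth": truth,
        "train": full.subset(slice(0, N_TRAIN)),
        "heldout": full.subset(slice(N_TRAIN, N_TRAIN + N_HELDOUT)),
    }


@pytest.fixture(scope="session")
def trained_study(study):
    """The study's model trained for 200 epochs, with pre-training diagnostics."""
    train = study["train"]
    params = init_model(ModelConfig(seed=STUDY_SEED), norm_stats=train.norm_stats)
    cosine_init = mean_same_fp_cosine(params, study["heldout"].X, train.norm_stats)
    params, log = fit(train, params, TrainConfig(epochs=200, seed=STUDY_SEED))
    return {**study, "params": params, "log": log.to_frame(), "cosine_init": cosine_init}


@pytest.fixture()
def tiny_set():
    """A fast, small synthetic training set for structural tests."""
    ts, _ = generate_synthetic(SyntheticSpec(n_compounds=60, seed=3))
    return ts
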