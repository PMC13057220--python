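"""Shared fixtures.

The expensive end-to-end run (500 phantoms, 20-epoch CNN training) is a
session fixture so the full-pipeline checks and the trained-model
properties (uncertainty ordering, attention-map localization) all reuse a
single training.
"""

from __future__ import annotations

import numpy as np
import pytest

from organ_age import experiments, synthetic
from organ_age.config import TrainConfig


@pytest.fixture(scope="session")
def e2e():
    """Full-chain experiment results on one organ (trains the CNN once)."""
    return experiments.end_to_end_experiment(seed=1, return_artifacts=True)


@pytest.fixture(scope="session")
def small_cohort():
    return synthetic.generate_cohort(300, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def tiny_train_config():
    return TrainConfig(epochs=2, batch_size=8, channels=(4, 8), seed=0)
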