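"""Shared fixtures: synthetic study data and trained models.

The expensive fixtures (trained models on the planted-motif task) are
session-scoped so the learnability, ablation and interpretability tests
share three training runs.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from dppiv.data import MotifSpec, generate_synthetic, split_benchmark
from dppiv.model import ModelConfig, ModelParams, train

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study_data():
    """Planted-motif synthetic set (n=400) with a stratified 80/20 split."""
    records = generate_synthetic(200, 200, MotifSpec(seed=STUDY_SEED))
    train_set, test_set = split_benchmark(records, 0.8, seed=STUDY_SEED)
    return train_set, test_set


@pytest.fixture(scope="session")
def trained_models(study_data):
    """Full, structural-only and text-only models trained on the same split."""
    train_set, _ = study_data
    models = {}
    for branch in ("both", "structural_only", "text_only"):
        config = ModelConfig.for_synthetic_study(seed=STUDY_SEED, branch=branch)
        models[branch] = train(train_set, config)
    return models


@pytest.fixture(scope="session")
def tiny_model():
    """A very small, quickly trained full model for structural/API tests."""
    config = ModelConfig(
        struct_channels=(4, 8),
        text_embed_dim=8,
        text_filters_per_width=4,
        fusion_dim=16,
        head_hidden=8,
        learning_rate=1e-3,
        batch_size=16,
        max_epochs=6,
        seed=7,
        max_residues=12,
    )
    records = generate_synthetic(20, 20, MotifSpec(length_range=(5, 12), seed=7))
    return train(records, config)


@pytest.fixture()
def untrained_tiny() -> ModelParams:
    config = ModelConfig(
        struct_channels=(4, 8),
        text_embed_dim=8,
        text_filters_per_width=4,
        fusion_dim=16,
        head_hidden=8,
        seed=3,
        max_residues=12,
    )
    return ModelParams(config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
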