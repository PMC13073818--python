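"""Shared fixtures: synthetic datasets and trained classifiers.

Training fixtures are session-scoped so the expensive fits (the separable
recovery runs) happen once and are shared by the behavioural and
acceptance tests.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from atpbind import SynthConfig, generate_dataset
from atpbind.dqn import DQNClassifier, DQNConfig
from atpbind.transformer import LocalGlobalTransformer, TransformerConfig

# desk-scale architecture: same structure as the published model but with a
# narrower projected width so the suite runs on one CPU
SMALL_T = dict(proj_dim=48, token_dim=8, heads=4, window=16)
TINY_T = dict(proj_dim=16, token_dim=4, heads=2, window=8)


@pytest.fixture(scope="session")
def separable_dataset():
    """~20k residues at 25:1 imbalance, strongly separated classes (dim 64)."""
    cfg = SynthConfig(
        n_chains=100, chain_length_range=(150, 250), dim=64,
        informative_dim=16, separation=6.0, seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def null_datasets():
    """Separation-0 train and independent ~10k-residue test draw."""
    base = SynthConfig(
        n_chains=50, chain_length_range=(150, 250), dim=64,
        informative_dim=16, separation=0.0, seed=21,
    )
    return generate_dataset(base), generate_dataset(replace(base, seed=22))


@pytest.fixture(scope="session")
def trained_transformer(separable_dataset):
    cfg = TransformerConfig(
        in_dim=64, max_epochs=5, patience=3, seed=3, **SMALL_T
    )
    return LocalGlobalTransformer.from_dataset(separable_dataset, cfg).fit()


@pytest.fixture(scope="session")
def trained_dqn(separable_dataset):
    cfg = DQNConfig(in_dim=64, episodes=30, seed=5)
    return DQNClassifier.from_dataset(separable_dataset, cfg).fit()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_dataset():
    """Small fast dataset (dim 16) for orchestration-level tests."""
    cfg = SynthConfig(
        n_chains=14, chain_length_range=(60, 100), dim=16,
        informative_dim=8, separation=5.0, seed=7,
    )
    return generate_dataset(cfg)
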