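"""Shared fixtures: small seeded synthetic datasets and model configs."""

import numpy as np
import pytest

from canopylai import synthdata
from canopylai.model import ModelConfig


@pytest.fixture(scope="session")
def small_config() -> synthdata.SceneConfig:
    """A coarse-resolution scene config sized for fast tests."""
    return synthdata.SceneConfig(
        n_points=24, resolution_cm=10.0, patch_size=24, seed=11
    )


@pytest.fixture(scope="session")
def clean_config() -> synthdata.SceneConfig:
    """Noise-free, gain/bias-free variant for deterministic link checks."""
    return synthdata.SceneConfig(
        n_points=6,
        resolution_cm=10.0,
        patch_size=24,
        texture_noise=0.0,
        gain_range=(1.0, 1.0),
        bias_range=(0.0, 0.0),
        point_sigma=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def benchmark_samples():
    """A 60-point labelled time-series dataset (reflectance patches)."""
    _, samples = synthdata.make_benchmark(n_points=60, seed=0)
    return samples


@pytest.fixture(scope="session")
def tiny_model_config() -> ModelConfig:
    """A shrunken hybrid that trains in seconds."""
    return ModelConfig(
        n_features=8,
        n_stages=3,
        cnn_filters=(8, 16),
        gru_units=(16, 8),
        meta_units=(16, 8),
        branch_head=8,
        dropout=0.0,
        max_epochs=150,
        patience=40,
        seed=0,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
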