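"""Shared fixtures: small synthetic bundles and trained models (session-scoped)."""

import numpy as np
import pytest

from trajsel.data import default_split
from trajsel.models import ArchitectureSpec, build_cnn1d, train_classifier
from trajsel.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_config():
    """A few-trajectory configuration for structural checks."""
    return GeneratorConfig(n_ligands=3, n_per_class=4, n_frames=120, master_seed=123)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config):
    bundle = generate_dataset(tiny_config)
    default_split(bundle, 2 / 3)
    bundle.fit_normalizer()
    return bundle


@pytest.fixture(scope="session")
def small_trained():
    """A 1D-CNN trained on a small temporal-signal dataset (good accuracy)."""
    cfg = GeneratorConfig(n_ligands=10, n_per_class=60, n_frames=400, master_seed=11)
    bundle = generate_dataset(cfg)
    default_split(bundle, 0.8)
    bundle.fit_normalizer()
    model = build_cnn1d(bundle.n_frames, bundle.n_channels, seed=1)
    trained = train_classifier(model, bundle, ArchitectureSpec.default("cnn1d", seed=1))
    return trained, bundle


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
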