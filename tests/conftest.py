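"""Shared fixtures: small synthetic datasets and trained desk-scale models.

Training fixtures are session-scoped; each takes a few seconds on one CPU
and is reused by the representation, evaluation and acceptance tests.
"""

import numpy as np
import pytest

from perturbvae import (
    SVQVAEConfig,
    SyntheticConfig,
    VAEConfig,
    simulate_dataset,
    simulate_drug_target_benchmark,
    train_svqvae,
    train_vae,
)


@pytest.fixture(scope="session")
def synth():
    """2000 samples, 100 genes, 8 well-separated drug classes, no twins."""
    cfg = SyntheticConfig(seed=1, target_link_fraction=0.0)
    data, truth = simulate_dataset(cfg)
    return data, truth


@pytest.fixture(scope="session")
def trained_vae(synth):
    data, _ = synth
    cfg = VAEConfig(input_dim=100, layer_sizes=(64, 64, 16), epochs=150,
                    batch_size=128, learning_rate=1e-3, seed=0)
    model, log = train_vae(data, cfg)
    return model, log


@pytest.fixture(scope="session")
def trained_svqvae(synth):
    data, _ = synth
    cfg = SVQVAEConfig(input_dim=100, hidden_sizes=(64,), embedding_dim=32,
                       n_classes=8, epochs=200, batch_size=64,
                       learning_rate=1e-3, seed=0)
    model, log = train_svqvae(data, cfg)
    return model, log


@pytest.fixture(scope="session")
def retrieval_benchmark():
    """Drug / knockdown-twin benchmark with 20 distractor genes."""
    cfg = SyntheticConfig(seed=3, samples_per_class=30,
                          n_distractor_classes=20)
    return simulate_drug_target_benchmark(cfg)
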