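"""Shared fixtures: small simulated data sets and one trained compression.

The expensive artefacts (trained VAE latent spaces) are session-scoped so
the whole suite trains each model once.
"""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from schae.latent_model import compress
from schae.preprocess import preprocess
from schae.synthetic import SimulationSpec, simulate_counts


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def groups3():
    """Small 3-group fixture: 600 cells x 2000 genes, 30% dropout."""
    spec = SimulationSpec(n_cells=600, n_genes=2000, n_groups=3, dropout_target=0.3, seed=3)
    mat, truth = simulate_counts(spec)
    return mat, truth


@pytest.fixture(scope="session")
def groups3_scaled(groups3):
    mat, truth = groups3
    return preprocess(mat), truth


@pytest.fixture(scope="session")
def groups3_latent(groups3_scaled):
    """Compressed latent space of the 3-group fixture (one VAE training)."""
    x, truth = groups3_scaled
    z, model = compress(x, seed=5)
    return z, model, truth


@pytest.fixture(scope="session")
def blobs_latent(rng):
    """Well-separated Gaussian blobs standing in for a latent space."""
    centers = rng.normal(0, 5, size=(4, 15))
    labels = np.repeat(np.arange(4), 50)
    z = centers[labels] + rng.normal(0, 0.3, size=(200, 15))
    return z, labels
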