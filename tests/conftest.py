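"""Shared fixtures: small synthetic coverage matrices and datasets."""

from __future__ import annotations

import numpy as np
import pytest

from degnorm.coverage import CoverageMatrix
from degnorm.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def proportional_gene(scales, shape, gene_id="g", samples=None):
    """Exactly rank-one coverage: row_j = scales[j] * shape."""
    scales = np.asarray(scales, dtype=float)
    shape = np.asarray(shape, dtype=float)
    F = np.outer(scales, shape)
    X = np.round(F.sum(axis=1)).astype(np.int64)
    samples = samples or [f"s{j}" for j in range(len(scales))]
    return CoverageMatrix(gene_id, samples, F, X, active=True)


@pytest.fixture
def proportional_dataset():
    """Ten exactly proportional genes across 4 samples with unequal depth."""
    rng = np.random.default_rng(7)
    scales = np.array([1.0, 2.0, 0.5, 1.5])
    covs = []
    for i in range(10):
        L = int(rng.integers(120, 400))
        shape = rng.uniform(1.0, 30.0, L)
        covs.append(proportional_gene(scales, shape, gene_id=f"g{i}"))
    return covs


@pytest.fixture(scope="session")
def small_sim_ii():
    """A small setting-II dataset with planted degradation."""
    cfg = SimulationConfig(
        n_genes=120, depth_range=(2.4e5, 3.6e5), setting="II", seed=42
    )
    return simulate_dataset(cfg)
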