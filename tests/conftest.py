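"""Shared fixtures: planted datasets and their consensus solutions.

The expensive artifacts (the 700-voxel default dataset and its c=7 / c=2
consensus solutions) are session-scoped so the recovery, hierarchy,
stability, and uncertainty checks all reuse one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import softparc as sp


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_dataset():
    """Default planted hierarchy: 7 networks x 100 voxels, 300 frames."""
    spec = sp.HierarchySpec(seed=7)
    ts, gt = sp.simulate_bold(spec)
    cmap = sp.correlation_map(ts)
    return spec, ts, gt, cmap


@pytest.fixture(scope="session")
def consensus7(default_dataset):
    """20-run consensus at c=7 on the default dataset, runs retained."""
    _, _, _, cmap = default_dataset
    sol, runs = sp.consensus_runs(cmap, 7, n_runs=20, rng_seed=101, return_runs=True)
    return sol, runs


@pytest.fixture(scope="session")
def consensus2(default_dataset):
    """10-run consensus at c=2 (the two-system solution)."""
    _, _, _, cmap = default_dataset
    return sp.consensus_runs(cmap, 2, n_runs=10, rng_seed=102)


@pytest.fixture(scope="session")
def small_dataset():
    """Cheap 4-network dataset for smoke-level checks."""
    spec = sp.HierarchySpec(
        n_networks=4, voxels_per_network=30, n_frames=150, seed=3
    )
    ts, gt = sp.simulate_bold(spec)
    cmap = sp.correlation_map(ts)
    return spec, ts, gt, cmap


def best_match_accuracy(hard: np.ndarray, truth: np.ndarray, k: int) -> float:
    """Fraction of voxels correct under the best one-to-one label matching."""
    from scipy.optimize import linear_sum_assignment

    conf = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            conf[i, j] = np.sum((truth == i) & (hard == j))
    rows, cols = linear_sum_assignment(-conf)
    return conf[rows, cols].sum() / len(hard)
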