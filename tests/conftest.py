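"""Shared fixtures. The expensive trained-score fixtures are session-scoped
so the acceptance tests and property tests reuse one training run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import spotcell as sc
from spotcell import benchmarks


@pytest.fixture(scope="session")
def benchmark_reference():
    """K=4, G=64 negative-binomial reference with profiles."""
    return benchmarks.make_benchmark_reference()


@pytest.fixture(scope="session")
def benchmark_prior(benchmark_reference):
    """Conditional score prior trained on the benchmark reference
    (desk-scale settings: L=50, 2000 epochs)."""
    _, ref, prof = benchmark_reference
    return benchmarks.train_benchmark_prior(ref, prof, seed=0)


@pytest.fixture(scope="session")
def score_study():
    """1-D Gaussian score-learning study (trains a small network once)."""
    return benchmarks.score_learning_study(seed=0)


@pytest.fixture()
def tiny_profile():
    """3-type, 8-gene profile with well separated markers."""
    rng = np.random.default_rng(11)
    means = sc.simulate.default_type_means(3, 8, rng, base_mean=2.0,
                                           marker_fold=6.0)
    spec = sc.SimulationSpec(n_types=3, n_genes=8, cells_per_type=[80] * 3,
                             means=means, seed=11)
    ref = sc.simulate_reference(spec)
    return sc.estimate_type_profiles(*ref)


@pytest.fixture()
def one_spot_dataset():
    coords = pd.DataFrame({"spot_id": ["s0"], "x": [0.0], "y": [0.0],
                           "slice": 0})
    counts = np.array([[3.0, 0.0, 1.0, 2.0, 0.0, 0.0, 1.0, 5.0]])
    return sc.SpotDataset(counts=counts, coords=coords,
                          cell_counts=np.array([3]))
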