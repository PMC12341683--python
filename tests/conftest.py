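"""Shared fixtures: small random survival datasets and the session-scoped
synthetic benchmark runs reused across pipeline-level tests."""

import numpy as np
import pytest

from kansurv.benchmark import FAMILIES, run_family
from kansurv.data import SurvivalDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_survival_arrays(rng, n=50, p=3, censor_frac=0.3, theta=None):
    """Random covariates with exponential event times and uniform censoring."""
    X = rng.uniform(-1, 1, (n, p))
    th = np.zeros(n) if theta is None else theta(X)
    T = rng.exponential(1.0 / (0.05 * np.exp(th)))
    C = rng.uniform(0, np.quantile(T, 1 - censor_frac) * 2, n)
    t = np.minimum(T, C)
    delta = (T <= C).astype(float)
    if delta.sum() == 0:
        delta[0] = 1.0
    return X, t, delta


@pytest.fixture
def small_dataset(rng):
    X, t, delta = make_survival_arrays(rng, n=120, p=3)
    return SurvivalDataset(X, t, delta, ["x1", "x2", "x3"])


# benchmark problem sizes used by the test suite; the weak-signal "complex"
# family needs a larger sample for the regularizer to separate noise edges
BENCH_N = {"gaussian": 3000, "mixed": 3000, "euclidean": 3000, "complex": 6000}


@pytest.fixture(scope="session")
def benchmark_runs():
    """Full pipeline (train -> prune -> symbolize) on all four synthetic
    hazard families at test scale, seed 0, with models kept."""
    return {
        fam: run_family(
            fam, n_train=BENCH_N[fam], n_test=BENCH_N[fam], seed=0, keep_models=True
        )
        for fam in FAMILIES
    }
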