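import numpy as np
import pytest

from huberlasso.solver import RegressionProblem


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_problem(rng):
    """Well-conditioned n > p instance with a sparse signal."""
    n, p = 60, 8
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[0], beta[2] = 1.0, -0.6
    y = X @ beta + 0.5 * rng.normal(size=n)
    return RegressionProblem(y, X)


def make_problem(seed, n=30, p=8, snr=1.0):
    """Seeded random small instance used across solver tests."""
    r = np.random.default_rng(seed)
    X = r.normal(size=(n, p))
    beta = np.zeros(p)
    beta[: max(1, p // 4)] = r.normal(size=max(1, p // 4))
    y = snr * (X @ beta) + r.normal(size=n)
    return RegressionProblem(y, X)
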