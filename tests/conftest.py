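import numpy as np
import pandas as pd
import pytest

from crcsubtype import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_expr():
    """3 probes x 4 samples with known values."""
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0], [2.0, 0.0, 2.0, 0.0]],
        index=["pA", "pB", "pC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def random_expr(rng):
    """200 probes x 20 samples of nonnegative noise."""
    data = pd.DataFrame(
        rng.uniform(1.0, 10.0, (200, 20)),
        index=[f"p{i:03d}" for i in range(200)],
        columns=[f"s{j:02d}" for j in range(20)],
    )
    return ExpressionMatrix(data)


def planted_two_block(n_probes=120, n_per_block=8, effect=3.0, noise=1.0, seed=0):
    """Two sample blocks, disjoint up-regulated probe blocks; returns
    (ExpressionMatrix, true labels array)."""
    rng = np.random.default_rng(seed)
    m = 2 * n_per_block
    X = np.clip(rng.normal(7.0, noise, (n_probes, m)), 0, None)
    b = n_probes // 6
    X[:b, :n_per_block] += effect
    X[b : 2 * b, n_per_block:] += effect
    data = pd.DataFrame(
        X,
        index=[f"p{i:03d}" for i in range(n_probes)],
        columns=[f"s{j:02d}" for j in range(m)],
    )
    labels = np.array([0] * n_per_block + [1] * n_per_block)
    return ExpressionMatrix(data), labels
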