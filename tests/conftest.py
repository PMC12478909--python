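import numpy as np
import pandas as pd
import pytest

from causalhurdle.data import ObservationTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_table(n=50, p=4, seed=0, integer_weights=False):
    """Small random observation table for unit tests."""
    rng = np.random.default_rng(seed)
    cov = pd.DataFrame(
        {f"x{j}": rng.normal(size=n) for j in range(p - 1)}
        | {"b0": rng.integers(0, 2, n).astype(float)})
    d = rng.integers(0, 2, n)
    y = rng.poisson(1.0, n)
    w = rng.integers(1, 4, n).astype(float) if integer_weights else None
    return ObservationTable(cov, d, {"y": y}, w)


@pytest.fixture
def small_table():
    return random_table(n=50, p=4, seed=7)
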