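import numpy as np
import pytest
from hypothesis import settings

from youdenci import TwoGroupSample, load_prostate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def prostate() -> TwoGroupSample:
    return load_prostate()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def dense_grid_youden(x, y, points=10_000):
    """Independent brute-force Youden maximisation on a dense grid.

    Evaluates the step objective on an evenly spaced grid extending one
    unit beyond the data range (plus the exact data values, so jumps are
    never straddled).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    lo = min(x.min(), y.min()) - 1.0
    hi = max(x.max(), y.max()) + 1.0
    grid = np.union1d(np.linspace(lo, hi, points), np.concatenate([x, y]))
    # integer numerator over the common denominator m*n keeps the scan exact
    num = (x[:, None] <= grid).sum(axis=0) * y.size - (y[:, None] < grid).sum(axis=0) * x.size
    k = int(np.argmax(num))
    return float(num[k] / (x.size * y.size)), float(grid[k])
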