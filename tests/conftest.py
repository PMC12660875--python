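import numpy as np
import pandas as pd
import pytest

from splitwise import Dataset
from splitwise.encoding import EncodingMap, build_design
from splitwise.io import load_mtcars


@pytest.fixture(scope="session")
def mtcars() -> Dataset:
    return load_mtcars()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_numeric(rng) -> Dataset:
    """Three numeric predictors, y depends on the first two."""
    n = 60
    X = rng.standard_normal((n, 3))
    y = 1.5 * X[:, 0] - 2.0 * X[:, 1] + rng.normal(0, 0.5, n)
    frame = pd.DataFrame(X, columns=["a", "b", "c"])
    return Dataset(frame, pd.Series(y, name="y"))


def make_design(data: Dataset):
    """All-linear design for a dataset (helper used across test modules)."""
    return build_design(data, EncodingMap.all_linear(data))
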