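import numpy as np
import pandas as pd
import pytest

from halfcell import ExpressionMatrix


def make_matrix(values, unit="log2", features=None, cells=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"g{i + 1}" for i in range(values.shape[0])]
    cells = cells or [f"c{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=features, columns=cells), unit=unit)


@pytest.fixture
def small_log2():
    rng = np.random.default_rng(7)
    return make_matrix(rng.normal(0, 1, (20, 6)))


@pytest.fixture
def two_blob_matrix():
    """50 features, 12 cells in two well-separated groups (effect >> noise)."""
    rng = np.random.default_rng(11)
    base = rng.normal(0, 0.2, (50, 12))
    base[:25, 6:] += 5.0
    return make_matrix(base), np.array([1] * 6 + [2] * 6)
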