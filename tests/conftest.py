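import numpy as np
import pytest

from xdecsm.core_io import ExpressionMatrix
from xdecsm.transform import TransformedMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    values = np.array(
        [[0.0, 5.0], [10.0, 2.5], [20.0, 7.5]]
    )
    return ExpressionMatrix(values, ["gA", "gB", "gC"], ["s1", "s2"])


def make_transformed(values, scale_a=1.0):
    values = np.asarray(values, dtype=float)
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return TransformedMatrix(values, genes, samples, scale_a)


@pytest.fixture
def make_T():
    return make_transformed
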