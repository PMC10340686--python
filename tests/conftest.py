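import numpy as np
import pytest

from gges import Dataset, VariableSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20231201)


@pytest.fixture
def iid_dataset():
    """Five mutually independent standard-normal columns, n = 5000."""
    gen = np.random.default_rng(7)
    names = list("abcde")
    return Dataset(gen.standard_normal((5000, 5)), [VariableSpec(n) for n in names])


def random_dataset(names, n, seed, correlated=True):
    """A generic numeric dataset with mild cross-correlations."""
    gen = np.random.default_rng(seed)
    X = gen.standard_normal((n, len(names)))
    if correlated:
        mix = gen.normal(0.0, 0.4, size=(len(names), len(names)))
        np.fill_diagonal(mix, 1.0)
        X = X @ mix
    return Dataset(X, [VariableSpec(v) for v in names])
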