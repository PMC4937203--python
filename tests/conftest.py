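import numpy as np
import pytest

from kronstat import TransposableDataset


def make_dataset(n=5, r=6, c=3, seed=0, values=None):
    """Small labelled cube with reproducible standard-normal entries."""
    if values is None:
        values = np.random.default_rng(seed).standard_normal((n, r, c))
    values = np.asarray(values, dtype=float)
    n, r, c = values.shape
    return TransposableDataset(
        values,
        [f"s{i}" for i in range(n)],
        [f"g{a}" for a in range(r)],
        [f"t{b}" for b in range(c)],
    )


@pytest.fixture
def small_ds():
    return make_dataset()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
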