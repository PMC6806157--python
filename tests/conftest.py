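import numpy as np
import pytest

from pamonofreq.patch_io import FeatureTable, Patch


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_patch(rng):
    """One seeded random 32x32 patch."""
    return Patch(rng.uniform(0.0, 1.0, size=(32, 32)))


def random_table(rng, n=200, d=5, separable=True):
    """Labeled feature table; if separable, feature 0 determines the label."""
    values = rng.normal(size=(n, d))
    labels = (values[:, 0] > 0).astype(int) if separable else rng.integers(0, 2, n)
    if separable:
        values[:, 0] += np.where(labels == 1, 2.0, -2.0)
    return FeatureTable(values, [f"f{i}" for i in range(d)], labels)


@pytest.fixture
def separable_table(rng):
    return random_table(rng)
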