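import numpy as np
import pytest

from ctforensics import nn


@pytest.fixture
def float64_engine():
    """Run the NN engine in float64 for finite-difference gradient checks."""
    old = nn.DTYPE
    nn.set_dtype(np.float64)
    yield
    nn.set_dtype(old)


@pytest.fixture
def disk_patches():
    """Trivially separable patches: bright disk (positive) vs flat noise."""

    def make(n_per_class=100, size=16, seed=0):
        rng = np.random.default_rng(seed)
        neg = rng.normal(0.3, 0.05, size=(n_per_class, size, size))
        pos = rng.normal(0.3, 0.05, size=(n_per_class, size, size))
        yy, xx = np.mgrid[:size, :size]
        d2 = (yy - size / 2) ** 2 + (xx - size / 2) ** 2
        pos += 0.4 * np.exp(-d2 / (size * 0.8))[None]
        X = np.concatenate([neg, pos])
        y = np.concatenate([np.zeros(n_per_class, int), np.ones(n_per_class, int)])
        return X, y

    return make
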