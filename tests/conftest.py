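import numpy as np
import pytest

from gwproc import KernelSpec, WishartProcessConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240816)


@pytest.fixture
def rbf_spec():
    return KernelSpec("rbf", {"lengthscale": 0.35})


@pytest.fixture
def small_grid():
    return np.linspace(0.0, 1.0, 12)


@pytest.fixture
def small_config(rbf_spec):
    return WishartProcessConfig(d=2, v=3, kernel=rbf_spec)
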