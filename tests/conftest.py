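import numpy as np
import pytest

from dockvote import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """Small but clearly separable dataset for fast pipeline tests."""
    return sd.SyntheticSpec(
        n_active=20, n_inactive=80, n_features=10, effect_size=3.0, dock_gap=2.0, seed=7
    )


@pytest.fixture
def small_dataset(small_spec):
    return sd.gen_dataset(small_spec)


@pytest.fixture
def random_fingerprints(rng):
    def make(n, width=64, density=0.3):
        return (rng.random((n, width)) < density).astype(np.uint8)

    return make
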