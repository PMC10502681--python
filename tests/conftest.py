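import numpy as np
import pytest

from qsmpipe.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def small_spec():
    """Compact noiseless phantom without external sources (fast fixture)."""
    return PhantomSpec(grid_shape=(32, 32, 24), noise_sd=0.0,
                       background_sources=(), seed=42)


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return make_phantom(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240611)
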