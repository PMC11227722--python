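import numpy as np
import pytest

from fisherhab import synthgen


@pytest.fixture(scope="session")
def small_landscape():
    """A 1.5 x 1.5 km autocorrelated landscape shared across read-only tests."""
    return synthgen.generate_landscape(seed=42, extent=(1500.0, 1500.0),
                                       resolution=10.0,
                                       autocorrelation_range=150.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
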