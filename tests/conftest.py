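import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ramanbca import Spectrum, default_grid
from ramanbca.synthetic import default_library


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_spectrum(rng, grid):
    """A positive random spectrum on the default grid."""
    return Spectrum(grid, rng.uniform(0.0, 10.0, size=grid.size))
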