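import numpy as np
import pytest

from laryq.compensation import histogram_shift
from laryq.phantom import PhantomParams, make_phantom


@pytest.fixture(scope="session")
def default_sample():
    return make_phantom(PhantomParams(seed=1))


@pytest.fixture(scope="session")
def compensated_image(default_sample):
    return histogram_shift(default_sample.image)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
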