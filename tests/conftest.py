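import numpy as np
import pytest

from rbseg import PhantomParams, generate_phantom, healthy_references


@pytest.fixture(scope="session")
def half_shape():
    """Reduced working resolution used throughout the fast tests."""
    return (160, 240)


@pytest.fixture(scope="session")
def diseased_phantom(half_shape):
    return generate_phantom(3, PhantomParams(), shape=half_shape)


@pytest.fixture(scope="session")
def reference_grays(half_shape):
    return healthy_references(99, shape=half_shape)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
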