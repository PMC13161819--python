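import numpy as np
import pytest

from mindnet.geometry import generate_parcellation


@pytest.fixture(scope="session")
def small_geometry():
    """20 regions x ~30 vertices: enough structure, fast everywhere."""
    return generate_parcellation(20, 30, seed=0)


@pytest.fixture(scope="session")
def test_geometry():
    """The default synthetic scale: 60 regions, 50 vertices per region."""
    return generate_parcellation(60, 50, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
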