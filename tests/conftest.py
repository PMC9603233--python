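import numpy as np
import pytest

from spraymix.fixtures import water_h2o2_components
from spraymix.physchem import Environment


@pytest.fixture(scope="session")
def water_h2o2():
    """Water / hydrogen peroxide pair with the reference property values."""
    return water_h2o2_components()


@pytest.fixture(scope="session")
def room_env():
    """Reference environment: 293 K room, 283.8 K droplet surface."""
    return Environment(T_room=293.0, T_dr=283.8)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
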