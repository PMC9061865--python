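import numpy as np
import pytest

from nanorelease import NoiseSpec, ParticleGeometry, generate_profile
from nanorelease.tables import br_params_at, brd_params_at


@pytest.fixture(scope="session")
def geom():
    return ParticleGeometry()


@pytest.fixture(scope="session")
def br37():
    """Tabulated BR-model parameters at 37 degC."""
    return br_params_at(37)


@pytest.fixture(scope="session")
def brd37():
    """Tabulated BRD-model parameters at 37 degC."""
    return brd_params_at(37)


@pytest.fixture(scope="session")
def noiseless_br37_profile(br37):
    return generate_profile(br37, noise=NoiseSpec(sd=0.0))


@pytest.fixture(scope="session")
def dense_grid():
    return np.linspace(0.0, 40.0, 401)
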