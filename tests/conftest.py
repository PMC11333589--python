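import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from optidens.chromophores import default_library
from optidens.forward_model import Geometry, MediumModel, TimeAxis
from optidens.synthetic_cohort import synthetic_irf

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def fast_axis():
    """Coarse 1024-channel / 25 ps axis (25.6 ns span): resolves the IRF and
    the diffuse pulse at a fraction of the default 4096-channel cost."""
    return TimeAxis(n_channels=1024, dt=25e-12)


@pytest.fixture(scope="session")
def medium():
    return MediumModel()


@pytest.fixture(scope="session")
def fast_irf(fast_axis):
    return synthetic_irf(fast_axis)


@pytest.fixture(scope="session")
def reflectance_3cm():
    return Geometry(mode="reflectance", rho=3.0)


@pytest.fixture(scope="session")
def reflectance_2cm():
    return Geometry(mode="reflectance", rho=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
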