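import numpy as np
import pytest

from bgvbq.phantom import build_atlas, build_fiber_field, default_fiber_spec
from bgvbq.protocol import mpm_protocol


@pytest.fixture(scope="session")
def atlas():
    return build_atlas()


@pytest.fixture(scope="session")
def protocol():
    return mpm_protocol()


@pytest.fixture(scope="session")
def noiseless_field(atlas):
    return build_fiber_field(atlas, default_fiber_spec(atlas, dispersion_deg=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
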