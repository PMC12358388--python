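import numpy as np
import pytest

from ldvdose.aif import extract_aif
from ldvdose.phantom import PhantomSpec, make_phantom, simulate_study


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom(default_spec):
    return make_phantom(default_spec)


@pytest.fixture(scope="session")
def study(phantom, default_spec):
    """Noiseless forward-simulated study on the default 64x64x20 grid."""
    return simulate_study(phantom, default_spec)


@pytest.fixture(scope="session")
def artery_curve(study, phantom):
    return extract_aif(study, phantom.rois["artery"])


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
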