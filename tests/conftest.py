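import numpy as np
import pytest

from aperio.profiles import device_profile
from aperio.synth import Peak, SpectralParams, synth_recording


@pytest.fixture(scope="session")
def analytic_grid():
    """The 0.125 Hz spectral grid over the 1-40 Hz fit range."""
    return np.arange(1.0, 40.0 + 1e-9, 0.125)


@pytest.fixture(scope="session")
def alpha_params():
    """A typical child frontal spectrum: 1/f plus one alpha peak."""
    return SpectralParams(offset=1.0, exponent=1.5, peaks=(Peak(10.0, 0.6, 2.0),))


def make_recording(profile_name="emotiv_like", params=None, duration_s=240.0,
                   seed=0, **kwargs):
    profile = device_profile(profile_name)
    if params is None:
        params = SpectralParams(1.0, 1.5, (Peak(10.0, 0.6, 2.0),))
    half_params = {ch: (params, params) for ch in profile.channels}
    return synth_recording(half_params, profile, duration_s, seed=seed, **kwargs)


@pytest.fixture(scope="session")
def consumer_recording(alpha_params):
    rec, burst = make_recording("emotiv_like", alpha_params, seed=7)
    return rec, burst


@pytest.fixture(scope="session")
def research_recording(alpha_params):
    rec, burst = make_recording("biosemi_like", alpha_params, seed=8)
    return rec, burst


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
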