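import numpy as np
import pytest
from hypothesis import settings

from emdcombine import SiftConfig, SynthSpec, gen_series

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def two_tone():
    """512-point two-tone series: fast sin(2πt/16) + 0.5 sin(2πt/128)."""
    t = np.arange(512)
    fast = np.sin(2 * np.pi * t / 16)
    slow = 0.5 * np.sin(2 * np.pi * t / 128)
    return fast + slow, fast, slow


@pytest.fixture(scope="session")
def plain_cfg():
    """Single-member, noiseless sifting config (plain EMD)."""
    return SiftConfig(ensemble_size=1, noise_scale=0.0)


@pytest.fixture(scope="session")
def synth_series():
    return gen_series(SynthSpec(n=512, seed=3))
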