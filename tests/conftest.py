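import numpy as np
import pytest

from alphaband.simulate import EegSimConfig, Recording, generate_recording
from alphaband.spectra import STANDARD_GRID, CollapsedSpectrum


@pytest.fixture(scope="session")
def fast_config():
    """A 60-s recording config: enough epochs for stable spectra, cheap."""
    return EegSimConfig(duration=60.0, seed=7)


@pytest.fixture(scope="session")
def fast_recording(fast_config):
    return generate_recording(fast_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_collapsed(power):
    """Wrap an 87-value power array on the standard 2-45 Hz grid."""
    return CollapsedSpectrum(freqs=STANDARD_GRID.copy(),
                             power=np.asarray(power, dtype=float))


@pytest.fixture
def collapsed_factory():
    return make_collapsed
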