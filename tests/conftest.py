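import numpy as np
import pytest

from assrkit.io import EpochsSet

FS = 2000.0


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def times():
    """2 s epoch time axis, train onset at t=0."""
    return -1.0 + np.arange(int(2 * FS)) / FS


@pytest.fixture()
def tone_epochs(times):
    """Five identical pure 40 Hz unit-amplitude trials."""
    tone = np.sin(2 * np.pi * 40.0 * times)
    return EpochsSet(np.tile(tone, (5, 1)), FS, -1.0, stim_rate_hz=40.0)


@pytest.fixture()
def noise_epochs(rng):
    """100 unit-variance white-noise trials (no stimulus structure)."""
    return EpochsSet(rng.standard_normal((100, int(2 * FS))), FS, -1.0,
                     stim_rate_hz=40.0)
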