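import math

import numpy as np
import pytest

from titinsted.profiler import IntensityProfile

SIG = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # FWHM -> sigma


def gaussian(x, center, height, fwhm, baseline=0.0):
    s = fwhm * SIG
    return baseline + height * np.exp(-0.5 * ((x - center) / s) ** 2)


def make_profile(channels, span_nm=2000.0, pixel_nm=10.0, **metadata):
    """Build an IntensityProfile from {channel: [(center, height, fwhm), ...]}."""
    x = np.arange(0.0, span_nm + pixel_nm / 2, pixel_nm)
    chans = {}
    for name, peaks in channels.items():
        y = np.zeros_like(x)
        for center, height, fwhm in peaks:
            y = y + gaussian(x, center, height, fwhm)
        chans[name] = y
    metadata.setdefault("pixel_nm", pixel_nm)
    return IntensityProfile(positions=x, channels=chans, metadata=metadata)


@pytest.fixture
def noiseless_sim():
    """Jitter-free, noise-free simulated profile with ground truth."""
    from titinsted.simulate import StedSimParams, simulate_profile

    params = StedSimParams(registration_jitter_sd_nm=0.0, poisson_noise=False, seed=7)
    return simulate_profile(params)
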