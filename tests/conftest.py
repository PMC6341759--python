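import warnings

import numpy as np
import pytest

from csfpulse.synthetic import (
    WaveformParams,
    generate_flow_waveform,
    generate_pc_series,
    preset,
    simulate,
)


def make_series(name, seed=0, clean=False, **overrides):
    """Simulate a preset series; ``clean=True`` strips noise and offsets."""
    if clean:
        overrides.setdefault("noise_sd_phase_rad", 0.0)
        overrides.setdefault("noise_sd_magnitude", 0.0)
        overrides.setdefault("static_phase_offset_rad", 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # arterial aliasing
        return simulate(name, seed=seed, **overrides)


@pytest.fixture(scope="session")
def aqueduct_clean():
    return make_series("aqueduct", seed=0, clean=True)


@pytest.fixture(scope="session")
def aqueduct_noisy():
    return make_series("aqueduct", seed=0)


@pytest.fixture(scope="session")
def cistern_noisy():
    return make_series("cistern", seed=0)


@pytest.fixture(scope="session")
def aqueduct_waveform():
    wp = WaveformParams(period_s=60 / 69.2)
    return wp, generate_flow_waveform(wp, 30)
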