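import numpy as np
import pytest

from mariagait import preprocessing as pp
from mariagait import synthetic_gait as sg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sober_params():
    return sg.default_presets()["sober"]


@pytest.fixture
def clean_params():
    """Noise-free, jitter-free parameters with an integer-sample stride."""
    return sg.GaitClassParams(label="sober", step_rate_hz=2.0,
                              stride_time_cv=0.0, sway_amp=0.5,
                              harmonic_weights=(1.5, 0.5, 0.2), noise_sd=0.0)


@pytest.fixture
def small_seg_config():
    return pp.SegmentationConfig(resample_len=64)


@pytest.fixture
def recording(sober_params):
    return sg.generate_recording(sober_params, duration_s=10.0, fs=50.0,
                                 seed=7)


@pytest.fixture
def cycles(recording, small_seg_config):
    out = pp.preprocess_recording(recording, small_seg_config)
    assert out, "fixture recording must yield cycles"
    return out
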