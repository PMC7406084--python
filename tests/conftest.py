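import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from reefscape import CalibratedSegment, CalibrationSpec

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")

T0 = pd.Timestamp("2018-09-20T00:00:00")


@pytest.fixture
def cal() -> CalibrationSpec:
    """The deployed hydrophone: -174.5 dB re V/uPa, no extra gain, 16 bit."""
    return CalibrationSpec(sensitivity_db_re_v_per_upa=-174.5)


@pytest.fixture
def make_tone():
    """Factory for a calibrated pure-tone segment of given rms pressure."""

    def _make(freq_hz: float, rms_pa: float = 1.0, duration_s: float = 4.0,
              fs: float = 48000.0) -> CalibratedSegment:
        t = np.arange(int(duration_s * fs)) / fs
        x = rms_pa * np.sqrt(2) * np.sin(2 * np.pi * freq_hz * t)
        return CalibratedSegment(x, fs, T0, "tone")

    return _make


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20180920)
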