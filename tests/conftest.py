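import numpy as np
import pytest

from emdecg import Signal, SiftConfig, SyntheticECGSpec, synth_ecg


@pytest.fixture(scope="session")
def sift_cfg():
    return SiftConfig()


@pytest.fixture(scope="session")
def short_ecg():
    """10 s synthetic ECG at 360 Hz — fast enough for per-test decomposition."""
    return synth_ecg(SyntheticECGSpec(duration_s=10.0, seed=11))


@pytest.fixture(scope="session")
def default_ecg():
    """The generator's default conditions: 30 s, 360 Hz, 72 bpm."""
    return synth_ecg(SyntheticECGSpec(seed=1))


@pytest.fixture(scope="session")
def two_tone():
    """50 Hz + 2 Hz tones at 1 kHz: well-separated scales for EMD."""
    fs = 1000.0
    t = np.arange(int(5 * fs)) / fs
    hi = np.sin(2 * np.pi * 50.0 * t)
    lo = np.sin(2 * np.pi * 2.0 * t)
    return Signal(hi + lo, fs, name="two_tone"), hi, lo


def interior(n, frac=0.8):
    """Slice selecting the interior `frac` of an n-sample record."""
    margin = int(round(n * (1 - frac) / 2))
    return slice(margin, n - margin)
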