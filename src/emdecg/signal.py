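"""The basic sampled-signal container used throughout the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Signal:
    """A finite, uniformly sampled real-valued signal.

    Parameters
    ----------
    samples
        Amplitude samples (mV by convention for ECG).  Stored as a float64
        array; must be finite and at least 3 samples long.
    fs
        Sampling rate in Hz, strictly positive.
    name
        Free-text label carried through processing steps.
    """

    samples: np.ndarray
    fs: float
    name: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 3:
            raise ValueError("signal must contain at least 3 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must all be finite")
        self.fs = float(self.fs)
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        """Record duration in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray, suffix: str = "") -> "Signal":
        """Return a new Signal sharing fs/name (optionally suffixed)."""
        return Signal(samples=samples, fs=self.fs, name=self.name + suffix)
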