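"""Synthetic ECG beats and the three contaminating noise processes.

The ECG model is a sum of five Gaussian deflections (P, Q, R, S, T) per
beat on a quasi-periodic beat grid; it is a deliberately simple,
deterministic surrogate for clinical recordings whose morphology
parameters are directly testable.  Noise generators cover white Gaussian
noise, EMG-like band-limited broadband noise, 50/60 Hz powerline
interference, and respiratory baseline drift; :func:`mix_at_snr` scales a
noise realisation so the mixture hits an exact whole-record SNR target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .signal import Signal


@dataclass(frozen=True)
class WaveParams:
    """One ECG deflection: amplitude (mV), beat-relative centre, width (s)."""

    amplitude: float
    center_offset: float
    width: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError("wave width must be positive")
        if not 0.0 <= self.center_offset < 1.0:
            raise ValueError("center_offset must be in [0, 1)")


def default_wave_params() -> dict:
    """Default five-wave beat morphology (visually plausible lead-II-like)."""
    return {
        "P": WaveParams(0.15, 0.10, 0.025),
        "Q": WaveParams(-0.10, 0.22, 0.010),
        "R": WaveParams(1.00, 0.25, 0.012),
        "S": WaveParams(-0.15, 0.28, 0.010),
        "T": WaveParams(0.30, 0.45, 0.060),
    }


@dataclass(frozen=True)
class SyntheticECGSpec:
    """Parametric description of a synthetic ECG record.

    Defaults follow the MIT-BIH convention of 360 Hz sampling; the beat
    period is 60/heart_rate_bpm, perturbed per beat by a multiplicative
    uniform(+/-rr_jitter_frac) factor (mild physiological RR variability).
    """

    fs: float = 360.0
    duration_s: float = 30.0
    heart_rate_bpm: float = 72.0
    wave_params: dict = field(default_factory=default_wave_params)
    rr_jitter_frac: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.fs > 0 and self.duration_s > 0 and self.heart_rate_bpm > 0):
            raise ValueError("fs, duration_s and heart_rate_bpm must be positive")
        if self.rr_jitter_frac < 0:
            raise ValueError("rr_jitter_frac must be >= 0")
        for key in ("P", "Q", "R", "S", "T"):
            if key not in self.wave_params:
                raise ValueError(f"missing wave '{key}'")
        w = self.wave_params
        if not (
            w["R"].amplitude > abs(w["Q"].amplitude)
            and w["R"].amplitude > abs(w["S"].amplitude)
        ):
            raise ValueError("R amplitude must exceed |Q| and |S| amplitudes")


@dataclass(frozen=True)
class NoiseSpec:
    """Parametric description of one noise process.

    kind: "gaussian" (iid standard normal), "emg" (band-limited white
    noise), "powerline" (mains sinusoid, random phase), "baseline" (slow
    respiratory sinusoid, random phase) or "emg+gaussian" (equal-power
    sum of the first two).  Noise is returned *unscaled*;
    :func:`mix_at_snr` applies the SNR-exact gain.
    """

    kind: str
    target_snr_db: float = 0.0
    powerline_hz: float = 50.0
    emg_band_hz: tuple | None = None  # defaults to (20, min(500, 0.45*fs))
    baseline_hz: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in (
            "gaussian", "emg", "powerline", "baseline", "emg+gaussian"
        ):
            raise ValueError(f"unknown noise kind '{self.kind}'")
        if not self.powerline_hz > 0:
            raise ValueError("powerline_hz must be positive")
        if not self.baseline_hz > 0:
            raise ValueError("baseline_hz must be positive")


def synth_ecg(spec: SyntheticECGSpec) -> Signal:
    """Generate a synthetic ECG record (deterministic for a fixed seed)."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    x = np.zeros(n)
    period = 60.0 / spec.heart_rate_bpm
    onset = 0.0
    while onset < spec.duration_s + period:
        jitter = rng.uniform(-spec.rr_jitter_frac, spec.rr_jitter_frac)
        beat_period = period * (1.0 + jitter)
        for wave in spec.wave_params.values():
            center = onset + wave.center_offset * beat_period
            # 6-sigma support keeps the per-beat cost bounded
            lo = max(0, int(np.floor((center - 6 * wave.width) * spec.fs)))
            hi = min(n, int(np.ceil((center + 6 * wave.width) * spec.fs)) + 1)
            if hi <= lo:
                continue
            tt = t[lo:hi] - center
            x[lo:hi] += wave.amplitude * np.exp(-(tt * tt) / (2.0 * wave.width**2))
        onset += beat_period
    return Signal(samples=x, fs=spec.fs, name=f"synth_ecg(seed={spec.seed})")


def _bandlimit(white: np.ndarray, fs: float, low: float, high: float) -> np.ndarray:
    """Restrict white noise to [low, high] Hz by spectral masking (zero
    phase distortion, band power exact by construction)."""
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(white.size, d=1.0 / fs)
    spectrum[(freqs < low) | (freqs > high)] = 0.0
    return np.fft.irfft(spectrum, n=white.size)


def gen_noise(spec: NoiseSpec, n: int, fs: float) -> np.ndarray:
    """One unscaled noise realisation of length n at sampling rate fs."""
    if n < 2:
        raise ValueError("need at least 2 samples of noise")
    rng = np.random.default_rng(spec.seed)
    t = np.arange(n) / fs
    if spec.kind == "gaussian":
        return rng.standard_normal(n)
    if spec.kind in ("emg", "emg+gaussian"):
        band = spec.emg_band_hz or (20.0, min(500.0, 0.45 * fs))
        low, high = float(band[0]), float(band[1])
        if not 0 <= low < high < fs / 2:
            raise ValueError(f"EMG band {band} must satisfy 0 <= low < high < fs/2")
        emg = _bandlimit(rng.standard_normal(n), fs, low, high)
        if spec.kind == "emg":
            return emg
        white = rng.standard_normal(n)
        # equal-power sum; overall level is irrelevant (mix_at_snr rescales)
        return emg / np.sqrt(np.mean(emg**2)) + white / np.sqrt(np.mean(white**2))
    if spec.kind == "powerline":
        if spec.powerline_hz >= fs / 2:
            raise ValueError("powerline frequency exceeds Nyquist")
        phase = rng.uniform(0.0, 2.0 * np.pi)
        return np.sin(2.0 * np.pi * spec.powerline_hz * t + phase)
    # baseline drift
    if spec.baseline_hz >= fs / 2:
        raise ValueError("baseline frequency exceeds Nyquist")
    phase = rng.uniform(0.0, 2.0 * np.pi)
    return np.sin(2.0 * np.pi * spec.baseline_hz * t + phase)


def mix_at_snr(
    clean: Signal, noise, target_snr_db: float
) -> tuple[Signal, np.ndarray]:
    """Scale noise so that clean + noise has exactly the target SNR.

    The gain is alpha = sqrt(E_clean / (E_noise * 10^(SNR/10))), computed
    over the whole record.  Returns the corrupted Signal and the scaled
    noise actually added.
    """
    noise = np.asarray(noise, dtype=np.float64)
    if noise.size != len(clean):
        raise ValueError("clean and noise must have equal length")
    ec = float(np.sum(clean.samples**2))
    en = float(np.sum(noise**2))
    if ec == 0.0 or en == 0.0:
        raise ValueError("zero-energy clean signal or noise")
    alpha = np.sqrt(ec / (en * 10.0 ** (target_snr_db / 10.0)))
    scaled = alpha * noise
    corrupted = clean.with_samples(
        clean.samples + scaled, suffix=f"+noise@{target_snr_db:g}dB"
    )
    return corrupted, scaled


def write_fixture(signal: Signal, path, spec=None) -> None:
    """Write a signal as CSV plus a JSON sidecar recording its provenance.

    The sidecar (same stem, .json) holds the generating spec fields when a
    spec is given, and always the sampling rate and name.
    """
    from .io import write_signal_csv

    path = Path(path)
    write_signal_csv(signal, path)
    meta = {"fs": signal.fs, "name": signal.name, "n_samples": len(signal)}
    if spec is not None:
        fields = dict(spec.__dict__) if not isinstance(spec, dict) else dict(spec)
        meta["spec"] = {
            k: (
                {w: vars(p) for w, p in v.items()}
                if isinstance(v, dict) and v and isinstance(next(iter(v.values())), WaveParams)
                else v
            )
            for k, v in fields.items()
        }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))
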