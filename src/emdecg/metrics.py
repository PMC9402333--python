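"""Denoising performance metrics: SNR improvement, MSE and PRD.

All three compare a denoised estimate against the known clean signal:

    SNRimp = 10 log10( sum(corrupted - clean)^2 / sum(denoised - clean)^2 )
    MSE    = (1/N) sum (clean - denoised)^2
    PRD    = sqrt( sum(clean - denoised)^2 / sum clean^2 )

PRD is returned as a ratio; multiply by 100 for the conventional percent
figure.  Degenerate SNR cases return +/-inf sentinels so Monte-Carlo
aggregation can drop them instead of aborting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MetricsReport:
    """Eq-style metric bundle for one denoising trial."""

    snr_improvement_db: float
    mse: float
    prd: float
    input_snr_db: float


def _as_equal_arrays(*seqs):
    arrs = [np.asarray(s, dtype=np.float64) for s in seqs]
    n = arrs[0].size
    for a in arrs:
        if a.size != n:
            raise ValueError("sequences must have equal length")
    return arrs


def snr_improvement(original, corrupted, denoised) -> float:
    """Output SNR improvement in dB.

    10*log10 of corrupted-error energy over denoised-error energy.
    Returns +inf when the reconstruction is perfect and -inf when the
    "corrupted" input already equals the original (both logged as
    degenerate by the evaluation harness).
    """
    o, c, d = _as_equal_arrays(original, corrupted, denoised)
    num = float(np.sum((c - o) ** 2))
    den = float(np.sum((d - o) ** 2))
    if den == 0.0:
        return 0.0 if num == 0.0 else float("inf")
    if num == 0.0:
        return float("-inf")
    return 10.0 * np.log10(num / den)


def mse(original, estimate) -> float:
    """Mean squared error (1/N) sum (original - estimate)^2."""
    o, e = _as_equal_arrays(original, estimate)
    if o.size < 1:
        raise ValueError("need at least one sample")
    return float(np.mean((o - e) ** 2))


def prd(original, estimate) -> float:
    """Root of error energy over signal energy (dimensionless ratio)."""
    o, e = _as_equal_arrays(original, estimate)
    denom = float(np.sum(o * o))
    if denom == 0.0:
        raise ValueError("original signal has zero energy; PRD undefined")
    return float(np.sqrt(np.sum((o - e) ** 2) / denom))


def input_snr(clean, noise) -> float:
    """SNR of a clean/noise pair in dB: 10 log10(E_clean / E_noise)."""
    c, n = _as_equal_arrays(clean, noise)
    ec = float(np.sum(c * c))
    en = float(np.sum(n * n))
    if ec == 0.0 or en == 0.0:
        raise ValueError("zero-energy input; SNR undefined")
    return 10.0 * float(np.log10(ec / en))
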