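"""Empirical mode decomposition (EMD) by envelope-mean sifting.

EMD decomposes a signal x(t) into a small set of intrinsic mode functions
(IMFs) c_1..c_K of decreasing oscillation rate plus a near-monotonic
residue r, by repeatedly subtracting the mean of the cubic-spline upper
and lower envelopes (sifting).  An IMF is accepted when the normalised
standard difference (NSD) between consecutive sift iterates falls below a
threshold *and* the iterate satisfies the extrema / zero-crossing balance
criterion.  The cascade is complete by construction:

    x = c_1 + c_2 + ... + c_K + r        (exactly, up to float rounding)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

STOP_MONOTONIC = "monotonic_residue"
STOP_MAX_IMFS = "max_imfs"
STOP_INSUFFICIENT = "insufficient_extrema"


class InsufficientExtremaError(ValueError):
    """Raised when a sequence has too few extrema to build an envelope."""


@dataclass(frozen=True)
class SiftConfig:
    """Tuning knobs for sifting.

    nsd_threshold
        Convergence cut on the per-sample ratio sum
        NSD = sum_t (f_prev(t) - f_cur(t))^2 / f_cur(t)^2.
        0.2 is the conventional sifting value.
    max_sift_iters
        Hard cap on sift iterations per IMF.  On long records the
        per-sample NSD sum rarely dips below the threshold, so this cap is
        the effective stop.  Thorough sifting (50) drains weak
        high-frequency noise completely into the first IMFs, which keeps
        QRS energy out of them — the property the adaptive selection
        relies on.
    max_imfs
        Hard cap on the number of extracted IMFs.
    boundary_extrema
        Number of extrema mirrored about each endpoint before spline
        fitting, to suppress envelope end swings.
    zero_floor
        Relative denominator guard for the NSD ratio: samples with
        |f_cur| < zero_floor * RMS(f_cur) are skipped.
    """

    nsd_threshold: float = 0.2
    max_sift_iters: int = 50
    max_imfs: int = 12
    boundary_extrema: int = 2
    zero_floor: float = 1e-10

    def __post_init__(self) -> None:
        if not self.nsd_threshold > 0:
            raise ValueError("nsd_threshold must be positive")
        if self.max_sift_iters < 1:
            raise ValueError("max_sift_iters must be >= 1")
        if self.max_imfs < 1:
            raise ValueError("max_imfs must be >= 1")
        if self.boundary_extrema < 0:
            raise ValueError("boundary_extrema must be >= 0")
        if self.zero_floor < 0:
            raise ValueError("zero_floor must be >= 0")


@dataclass
class Decomposition:
    """Ordered IMFs (index 1 = highest frequency) plus the final residue.

    ``imfs[k-1]`` is the 1-based IMF c_k.  Every IMF and the residue has
    the source length, and their sum reproduces the source exactly up to
    float rounding (the cascade is a pure subtraction chain).
    """

    imfs: list
    residue: np.ndarray
    source_length: int
    stop_reason: str
    sift_counts: list = field(default_factory=list)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def sum(self) -> np.ndarray:
        """Reconstruct the source: sum of all IMFs plus the residue."""
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


def find_extrema(samples) -> tuple[np.ndarray, np.ndarray]:
    """Locate strictly interior local maxima and minima.

    Plateaus (runs of equal samples) count once, at the first index of the
    run.  Merged in index order, maxima and minima strictly alternate.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 3:
        raise ValueError("need at least 3 samples to locate extrema")
    # collapse plateaus to their first index so neighbour comparisons are strict
    keep = np.empty(x.size, dtype=bool)
    keep[0] = True
    keep[1:] = x[1:] != x[:-1]
    idx = np.flatnonzero(keep)
    if idx.size < 3:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    d = np.sign(np.diff(x[idx]))
    maxima = idx[1:-1][(d[:-1] > 0) & (d[1:] < 0)]
    minima = idx[1:-1][(d[:-1] < 0) & (d[1:] > 0)]
    return maxima, minima


def _mirror_knots(
    indices: np.ndarray, values: np.ndarray, n: int, n_mirror: int
) -> tuple[np.ndarray, np.ndarray]:
    """Reflect up to n_mirror extrema about each endpoint of [0, n-1]."""
    xs = [indices.astype(np.float64)]
    ys = [values]
    if n_mirror > 0 and indices.size > 0:
        k = min(n_mirror, indices.size)
        xs.append(-indices[:k][::-1].astype(np.float64))
        ys.append(values[:k][::-1])
        xs.append(2.0 * (n - 1) - indices[-k:][::-1].astype(np.float64))
        ys.append(values[-k:][::-1])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    x, first = np.unique(x, return_index=True)
    return x, y[first]


def build_envelope(samples, extrema_indices, side: str, cfg: SiftConfig) -> np.ndarray:
    """Cubic-spline envelope through the given extrema.

    Extrema are mirrored about each endpoint (``cfg.boundary_extrema`` per
    end) before fitting, and the spline is evaluated at every sample.  With
    fewer than 4 knots a natural spline is used (2 knots = straight line).
    """
    x = np.asarray(samples, dtype=np.float64)
    e = np.asarray(extrema_indices, dtype=np.intp)
    if e.size == 0:
        raise InsufficientExtremaError(f"no extrema for {side} envelope")
    knots_x, knots_y = _mirror_knots(e, x[e], x.size, cfg.boundary_extrema)
    if knots_x.size < 2:
        raise InsufficientExtremaError(
            f"only {knots_x.size} knot(s) for {side} envelope"
        )
    bc = "not-a-knot" if knots_x.size >= 4 else "natural"
    spline = CubicSpline(knots_x, knots_y, bc_type=bc, extrapolate=True)
    return spline(np.arange(x.size, dtype=np.float64))


def sift_once(h, cfg: SiftConfig) -> tuple[np.ndarray, np.ndarray]:
    """One sifting step: subtract the mean of upper and lower envelopes.

    Returns ``(h_next, m)`` with ``m = (upper + lower) / 2`` and
    ``h_next = h - m``.  Raises InsufficientExtremaError when either
    envelope cannot be built.
    """
    h = np.asarray(h, dtype=np.float64)
    maxima, minima = find_extrema(h)
    upper = build_envelope(h, maxima, "upper", cfg)
    lower = build_envelope(h, minima, "lower", cfg)
    m = 0.5 * (upper + lower)
    return h - m, m


def nsd(f_prev, f_cur, zero_floor: float) -> float:
    """Normalised standard difference between consecutive sift iterates.

    NSD = sum_t (f_prev(t) - f_cur(t))^2 / f_cur(t)^2, summed over samples
    where |f_cur(t)| >= zero_floor * RMS(f_cur); the ratio is undefined at
    zeros, so those samples are skipped.
    """
    a = np.asarray(f_prev, dtype=np.float64)
    b = np.asarray(f_cur, dtype=np.float64)
    if a.shape != b.shape or a.size < 1:
        raise ValueError("sequences must have equal nonzero length")
    rms = float(np.sqrt(np.mean(b * b)))
    if rms == 0.0:
        raise ValueError("current iterate is identically zero; NSD undefined")
    mask = np.abs(b) >= zero_floor * rms
    if not np.any(mask):
        raise ValueError("no valid denominators for NSD")
    diff = a[mask] - b[mask]
    return float(np.sum(diff * diff / (b[mask] * b[mask])))


def _zero_crossings(x: np.ndarray) -> int:
    """Sign changes between consecutive samples; exact zeros are dropped so
    a zero sample shared between opposite signs counts once."""
    s = x[x != 0.0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.sign(s[1:]) != np.sign(s[:-1])))


def is_imf(samples) -> bool:
    """Extrema / zero-crossing balance test for an intrinsic mode function.

    True iff the total number of extrema and the number of zero crossings
    differ by at most one.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    maxima, minima = find_extrema(x)
    n_ext = maxima.size + minima.size
    return abs(n_ext - _zero_crossings(x)) <= 1


def extract_imf(residual, cfg: SiftConfig) -> tuple[np.ndarray, int]:
    """Sift a residual until it qualifies as an IMF.

    Repeats :func:`sift_once` until the NSD between consecutive iterates
    drops below ``cfg.nsd_threshold`` *and* the iterate passes
    :func:`is_imf`, or ``cfg.max_sift_iters`` is reached.  When the cap is
    hit with the final iterate failing the mode criterion, the most recent
    iterate that did satisfy it is returned instead (sifting drifts in and
    out of validity; an extraction must deliver a valid mode).
    InsufficientExtremaError on the first sift propagates (the
    decomposition must stop); if sifting degenerates later, the current
    iterate is returned as-is.
    """
    h = np.asarray(residual, dtype=np.float64)
    count = 0
    last_valid = None
    while count < cfg.max_sift_iters:
        try:
            h_next, _ = sift_once(h, cfg)
        except InsufficientExtremaError:
            if count == 0:
                raise
            break
        count += 1
        try:
            stat = nsd(h, h_next, cfg.zero_floor)
        except ValueError:
            # iterate collapsed to (near) zero: nothing left to sift
            h = h_next
            break
        h = h_next
        valid = is_imf(h)
        if valid:
            last_valid = h
        if stat < cfg.nsd_threshold and valid:
            break
    if last_valid is not None and not is_imf(h):
        h = last_valid
    return h, count


def decompose(signal, cfg: SiftConfig | None = None) -> Decomposition:
    """Full EMD of a :class:`~emdecg.signal.Signal`.

    The cascade x -> c_1, r_1 = x - c_1 -> c_2, ... continues until the
    residue has fewer than 2 interior extrema (near-monotonic), the IMF cap
    is reached, or an envelope cannot be built.  Degenerate inputs yield
    zero IMFs with residue = input.
    """
    if cfg is None:
        cfg = SiftConfig()
    residual = signal.samples.astype(np.float64).copy()
    src_rms = float(np.sqrt(np.mean(residual * residual)))
    imfs: list[np.ndarray] = []
    counts: list[int] = []
    stop = STOP_MAX_IMFS
    while len(imfs) < cfg.max_imfs:
        maxima, minima = find_extrema(residual)
        if maxima.size + minima.size < 2:
            stop = STOP_INSUFFICIENT if not imfs else STOP_MONOTONIC
            break
        try:
            imf, n_sifts = extract_imf(residual, cfg)
        except InsufficientExtremaError:
            stop = STOP_INSUFFICIENT
            break
        # an envelope-degenerate residual yields a numerically-zero "IMF"
        # while keeping its content: nothing more is extractable
        if float(np.sqrt(np.mean(imf * imf))) <= 1e-12 * src_rms:
            stop = STOP_MONOTONIC
            break
        imfs.append(imf)
        counts.append(n_sifts)
        residual = residual - imf
    return Decomposition(
        imfs=imfs,
        residue=residual,
        source_length=residual.size,
        stop_reason=stop,
        sift_counts=counts,
    )
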