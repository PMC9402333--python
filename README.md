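# emdecg — adaptive EMD-based ECG denoising

Electrocardiograms recorded outside a shielded lab are contaminated by
broadband muscle (EMG) artifact, white instrumentation noise, 50/60 Hz
mains interference and slow respiratory baseline wander.  Classical
fixed-band filters either leave noise inside the ECG band or blunt the
sharp QRS complex that carries most of the diagnostic information.
`emdecg` implements an adaptive, data-driven alternative built on
empirical mode decomposition (EMD), aimed at people who work with
single-channel ECG time series: biomedical-signal researchers, developers
of automated arrhythmia pipelines, and anyone who needs a transparent,
fully scriptable denoiser with an evaluation harness attached.

## The method

EMD sifts a signal x(t) into intrinsic mode functions (IMFs) of
decreasing oscillation rate plus a near-monotonic residue,

    x(t) = Σ_{k=1..K} c_k(t) + r(t),

by repeatedly subtracting the mean of the cubic-spline envelopes through
the local maxima and minima.  Sifting of each mode stops when the
normalised standard difference between consecutive iterates,
NSD = Σ_t (f_{i−1}(t) − f_i(t))² / f_i(t)², falls below a threshold
(default 0.2) *and* the iterate's extrema and zero-crossing counts differ
by at most one.

High-frequency noise concentrates in the first (fastest) IMFs and is
nearly zero-mean, while ECG-bearing modes pull the cumulative
reconstruction mean R_k = mean(c_1 + … + c_k) towards the record mean.
The denoiser therefore

1. flags as noise candidates the initial run of IMFs with |R_k| below an
   adaptive threshold τ (at most the first two IMFs),
2. confirms each candidate with a power test — an IMF holding a
   structural share (≥ 40 %) of the total IMF energy is QRS-bearing and
   is never discarded,
3. optionally strips baseline wander by detaching the residue and then
   the slowest IMFs while a piecewise segment-slope metric of the
   reconstruction keeps falling (only sub-1 Hz components are eligible;
   the record's DC level is preserved),
4. reconstructs ECĜ = Σ g_k·c_k (+ residue) from the per-IMF gains.

Performance is quantified against a known clean reference by the output
SNR improvement 10·log₁₀(Σ(ECG_corr − ECG)² / Σ(ECĜ − ECG)²), the mean
squared error, and the percentage root-mean-square difference
PRD = √(Σ(ECG − ECĜ)² / Σ ECG²).

Because clinical recordings cannot ship with a package, `emdecg`
includes a synthetic study bench: a five-wave (P, Q, R, S, T)
sum-of-Gaussians ECG generator with RR jitter, the four noise models, and
exact-SNR mixing, plus a seeded Monte-Carlo grid harness over
noise type × input SNR × repetitions.

## Worked example

```python
from emdecg import (SyntheticECGSpec, NoiseSpec, synth_ecg, gen_noise,
                    mix_at_snr, denoise, snr_improvement, prd)

clean = synth_ecg(SyntheticECGSpec(seed=1))            # 30 s, 360 Hz, 72 bpm
noise = gen_noise(NoiseSpec("gaussian", seed=42), len(clean), clean.fs)
corrupted, _ = mix_at_snr(clean, noise, target_snr_db=5.0)
res = denoise(corrupted)
print(res.noise_imf_indices)
print(snr_improvement(clean.samples, corrupted.samples, res.denoised.samples))
print(100 * prd(clean.samples, res.denoised.samples))
```

Running this (it is `examples/02_denoise_noisy_ecg.py`) prints

```
noise IMFs removed:      [1, 2]
baseline components:     none
cumulative means |R_k|:  0.0004 0.0006 0.0011 0.0016 ...
SNR improvement: +5.40 dB
MSE:             0.00329 mV^2
PRD:             30.2 %
```

The first two IMFs had near-zero cumulative means and a small energy
share, so they were classified as noise and dropped; the error energy of
the record fell by 5.4 dB relative to the corrupted input.  The other
`examples/` scripts walk through decomposition, baseline-wander removal
and the Monte-Carlo grid the same way.

A thin CLI mirrors the library:

```bash
emdecg synth --duration 30 --seed 1 -o ecg.csv
emdecg denoise -i noisy.csv --fs 360 -o denoised.csv --diagnostics diag.json
emdecg evaluate --noise gaussian,emg --snr 0,5,10,15 --reps 20 --seed 1 -o report.json
```

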