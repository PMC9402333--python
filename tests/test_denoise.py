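"""Tests for the adaptive noise-IMF selection and baseline removal."""

import numpy as np
import pytest
from scipy.signal import periodogram

from emdecg import (
    DenoiseConfig,
    NoiseSpec,
    RESIDUE_MARKER,
    Signal,
    SiftConfig,
    SyntheticECGSpec,
    cumulative_mean_profile,
    decompose,
    denoise,
    gen_noise,
    imf_powers,
    mix_at_snr,
    prd,
    reconstruct,
    remove_baseline,
    select_noise_imfs,
    slope_metric,
    snr_improvement,
    synth_ecg,
)
from emdecg.emd import Decomposition


def make_decomposition(imfs, residue):
    imfs = [np.asarray(i, dtype=float) for i in imfs]
    residue = np.asarray(residue, dtype=float)
    return Decomposition(
        imfs=imfs,
        residue=residue,
        source_length=residue.size,
        stop_reason="monotonic_residue",
        sift_counts=[1] * len(imfs),
    )


def band_power(x, fs, lo=0.0, hi=0.5):
    f, p = periodogram(x - np.mean(x), fs)
    return float(np.sum(p[(f >= lo) & (f <= hi)]))


class TestCumulativeMeanAndPower:
    def test_partial_sum_means(self):
        d = make_decomposition([[1, 1], [3, 3]], [0, 0])
        assert np.allclose(cumulative_mean_profile(d), [1.0, 4.0])

    def test_mean_linearity_with_residue(self, short_ecg, sift_cfg):
        d = decompose(short_ecg, sift_cfg)
        R = cumulative_mean_profile(d)
        assert R[-1] + np.mean(d.residue) == pytest.approx(
            np.mean(short_ecg.samples), abs=1e-10
        )

    def test_powers_are_sums_of_squares(self):
        d = make_decomposition([[0, 0, 0, 0], [1, -1, 1, -1]], [0, 0, 0, 0])
        assert np.allclose(imf_powers(d), [0.0, 4.0])

    def test_empty_decomposition_rejected(self):
        d = make_decomposition([], [1, 2, 3])
        with pytest.raises(ValueError):
            cumulative_mean_profile(d)
        with pytest.raises(ValueError):
            imf_powers(d)


class TestSelectNoiseImfs:
    # x with mean 1.0 -> tau = 0.5 under the default factor
    X = np.ones(8)

    def test_small_mean_small_power_is_removed(self):
        idx, gains = select_noise_imfs(
            [0.0, 0.9], [0.001, 10.0], self.X, DenoiseConfig()
        )
        assert idx == [1]
        assert gains == [0.0, 1.0]

    def test_large_means_keep_everything(self):
        idx, gains = select_noise_imfs(
            [0.9, 1.2, 2.0], [1.0, 1.0, 1.0], self.X, DenoiseConfig()
        )
        assert idx == []
        assert gains == [1.0, 1.0, 1.0]

    def test_cap_limits_removal_to_first_two(self):
        idx, _ = select_noise_imfs(
            [0.0, 0.0, 0.0], [1e-6, 1e-6, 1.0], self.X, DenoiseConfig()
        )
        assert idx == [1, 2]

    def test_prefix_rule_blocks_mid_band_removal(self):
        # IMF1 fails the mean test, so IMF2 cannot be a candidate either
        idx, _ = select_noise_imfs(
            [0.9, 0.0], [1e-6, 1e-6], self.X, DenoiseConfig()
        )
        assert idx == []

    def test_power_veto_protects_dominant_imf(self):
        idx, _ = select_noise_imfs(
            [0.0, 0.0], [10.0, 0.1], self.X, DenoiseConfig()
        )
        assert idx == [2]

    def test_proportional_mode_soft_gain(self):
        cfg = DenoiseConfig(attenuation_mode="proportional")
        idx, gains = select_noise_imfs([0.25, 0.9], [0.001, 10.0], self.X, cfg)
        assert idx == [1]
        assert gains[0] == pytest.approx(0.5)  # |R|/tau = 0.25/0.5

    def test_zero_mean_record_uses_rms_fallback(self):
        x = np.array([1.0, -1.0] * 8)  # mean 0, RMS 1 -> tau = 0.5*0.01
        idx, _ = select_noise_imfs([0.001, 0.9], [1e-9, 1.0], x, DenoiseConfig())
        assert idx == [1]


class TestSlopeMetric:
    def test_zero_signal(self):
        assert slope_metric(np.zeros(100), 10.0, 1.0) == 0.0

    def test_global_ramp_sums_segment_slopes(self):
        fs, a, n_seg = 50.0, 0.7, 6
        t = np.arange(int(n_seg * fs)) / fs
        assert slope_metric(a * t, fs, 1.0) == pytest.approx(n_seg * a, abs=1e-9)

    def test_drift_strictly_inflates_metric(self, short_ecg):
        drift = gen_noise(
            NoiseSpec("baseline", baseline_hz=0.25, seed=9),
            len(short_ecg),
            short_ecg.fs,
        )
        with_drift = short_ecg.samples + 0.5 * drift
        assert slope_metric(with_drift, short_ecg.fs, 1.0) > slope_metric(
            short_ecg.samples, short_ecg.fs, 1.0
        )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            slope_metric([1.0], 10.0, 1.0)


class TestRemoveBaseline:
    def test_fast_oscillation_without_drift_keeps_everything(self):
        # single fast IMF, near-zero residue: only the residue is a candidate
        t = np.arange(400) / 100.0
        imf = np.sin(2 * np.pi * 10 * t)
        d = make_decomposition([imf], 1e-12 * np.ones(400))
        idx, traj = remove_baseline(d, 100.0, DenoiseConfig())
        assert idx == []
        assert len(traj) <= 2

    def test_strong_drift_is_stripped(self, short_ecg, sift_cfg):
        rms = float(np.sqrt(np.mean(short_ecg.samples**2)))
        drift = gen_noise(
            NoiseSpec("baseline", baseline_hz=0.2, seed=3),
            len(short_ecg),
            short_ecg.fs,
        )
        drift *= 3 * rms / np.sqrt(np.mean(drift**2))
        corrupted = short_ecg.with_samples(short_ecg.samples + drift)
        res = denoise(corrupted, sift_cfg, DenoiseConfig())
        assert res.baseline_imf_indices  # something was detached
        ratio = band_power(res.denoised.samples, short_ecg.fs) / band_power(
            corrupted.samples, short_ecg.fs
        )
        assert ratio <= 0.1

    def test_pure_trend_loses_residue(self):
        t = np.linspace(0, 1, 300)
        sig = Signal(2.0 * t, 300.0)
        res = denoise(sig, SiftConfig(), DenoiseConfig())
        assert RESIDUE_MARKER in res.baseline_imf_indices
        # trend removed: what remains is (close to) a constant level
        assert np.ptp(res.denoised.samples) < 0.05 * np.ptp(sig.samples)


class TestReconstruct:
    def test_unit_gains_reproduce_source(self, short_ecg, sift_cfg):
        d = decompose(short_ecg, sift_cfg)
        out = reconstruct(d, [1.0] * d.n_imfs, include_residue=True)
        scale = np.max(np.abs(short_ecg.samples))
        assert np.max(np.abs(out - short_ecg.samples)) <= 1e-8 * scale

    def test_zero_gains_without_residue_is_zero(self, short_ecg, sift_cfg):
        d = decompose(short_ecg, sift_cfg)
        assert np.allclose(
            reconstruct(d, [0.0] * d.n_imfs, include_residue=False), 0.0
        )

    def test_dropping_imf1_equals_subtraction(self, short_ecg, sift_cfg):
        d = decompose(short_ecg, sift_cfg)
        gains = [0.0] + [1.0] * (d.n_imfs - 1)
        out = reconstruct(d, gains, include_residue=True)
        assert np.allclose(out, short_ecg.samples - d.imfs[0], atol=1e-10)

    def test_gain_mismatch_rejected(self, short_ecg, sift_cfg):
        d = decompose(short_ecg, sift_cfg)
        with pytest.raises(ValueError):
            reconstruct(d, [1.0] * (d.n_imfs + 1), include_residue=True)

    def test_gain_linearity(self, short_ecg, sift_cfg):
        d = decompose(short_ecg, sift_cfg)
        rng = np.random.default_rng(1)
        g1 = rng.uniform(0, 1, d.n_imfs)
        g2 = rng.uniform(0, 1, d.n_imfs)
        lhs = reconstruct(d, g1, False) + reconstruct(d, g2, False)
        rhs = reconstruct(d, g1 + g2, False)
        assert np.allclose(lhs, rhs, atol=1e-10)


class TestDenoisePipeline:
    def test_clean_record_is_preserved(self, default_ecg):
        res = denoise(default_ecg)
        rho = np.corrcoef(default_ecg.samples, res.denoised.samples)[0, 1]
        assert rho > 0.99

    def test_gaussian_noise_improvement(self, default_ecg):
        wins = 0
        trials = 20
        for rep in range(trials):
            noise = gen_noise(
                NoiseSpec("gaussian", seed=500 + rep),
                len(default_ecg),
                default_ecg.fs,
            )
            corrupted, _ = mix_at_snr(default_ecg, noise, 5.0)
            res = denoise(corrupted)
            gain = snr_improvement(
                default_ecg.samples, corrupted.samples, res.denoised.samples
            )
            wins += gain > 0
        assert wins >= int(0.9 * trials)

    def test_constant_input_does_not_crash(self):
        res = denoise(Signal(np.full(100, 2.5), 100.0))
        assert len(res.denoised) == 100
        assert res.gains == []

    def test_identity_configuration(self, short_ecg):
        cfg = DenoiseConfig(power_fraction=1e-12, remove_baseline=False)
        res = denoise(short_ecg, None, cfg)
        scale = np.max(np.abs(short_ecg.samples))
        assert np.max(np.abs(res.denoised.samples - short_ecg.samples)) <= 1e-8 * scale

    def test_length_and_rate_preserved(self, short_ecg):
        res = denoise(short_ecg)
        assert len(res.denoised) == len(short_ecg)
        assert res.denoised.fs == short_ecg.fs

    def test_gains_are_unit_outside_modified_sets(self, default_ecg):
        noise = gen_noise(NoiseSpec("gaussian", seed=77), len(default_ecg), default_ecg.fs)
        corrupted, _ = mix_at_snr(default_ecg, noise, 5.0)
        res = denoise(corrupted)
        modified = set(res.noise_imf_indices) | set(res.baseline_imf_indices)
        for k, g in enumerate(res.gains, start=1):
            assert 0.0 <= g <= 1.0
            if k not in modified:
                assert g == 1.0

    def test_baseline_corrected_prd_improves(self, default_ecg):
        rms = float(np.sqrt(np.mean(default_ecg.samples**2)))
        drift = gen_noise(
            NoiseSpec("baseline", baseline_hz=0.2, seed=13),
            len(default_ecg),
            default_ecg.fs,
        )
        drift *= 3 * rms / np.sqrt(np.mean(drift**2))
        corrupted = default_ecg.with_samples(default_ecg.samples + drift)
        res = denoise(corrupted)
        assert prd(default_ecg.samples, res.denoised.samples) < prd(
            default_ecg.samples, corrupted.samples
        )
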