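"""Morlet CWT, ERP averaging, TF amplitude, phase, and the 10-bin
phase-synchronization statistic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from erpfuse.data_model import BaselineSpec, EpochedRecording, time_axis
from erpfuse.features import (
    FeatureSample,
    SpectralDecomposition,
    WaveletSpec,
    compute_erp,
    crop_tensor,
    cwt,
    cwt_direct,
    morlet_kernel,
    phase_bin_index,
    phase_sync_statistic,
    phase_synchronization,
    tf_phase,
    tf_power,
)

BASE = BaselineSpec()


class TestMorletKernel:
    def test_peak_is_real_positive_at_zero(self, wavelet):
        k = morlet_kernel(10.0, wavelet)
        mid = (k.size - 1) // 2
        assert k[mid].imag == 0.0
        assert k[mid].real > 0.0
        assert k[mid].real == np.abs(k).max()

    def test_envelope_symmetric(self, wavelet):
        k = morlet_kernel(6.0, wavelet)
        np.testing.assert_allclose(np.abs(k), np.abs(k[::-1]), rtol=1e-12)

    @pytest.mark.parametrize("f", [4.0, 10.0, 20.0])
    def test_fft_centre_frequency(self, f):
        # FFT oracle: the kernel's spectral peak sits at its analysis frequency
        spec = WaveletSpec(freqs=(f,), srate=150.0)
        k = morlet_kernel(f, spec)
        n_fft = 4096
        mags = np.abs(np.fft.fft(k, n_fft))
        freqs = np.fft.fftfreq(n_fft, 1 / 150.0)
        peak = freqs[np.argmax(mags)]
        assert abs(peak - f) <= 150.0 / n_fft

    def test_rejects_frequency_at_nyquist(self, wavelet):
        with pytest.raises(ValueError, match="Nyquist"):
            morlet_kernel(75.0, wavelet)


class TestCWT:
    def test_zero_signal_gives_zero_coefficients(self, wavelet):
        rec = EpochedRecording(np.zeros((2, 1, 451)), 150.0, (-1000.0, 2000.0),
                               ["rare", "frequent"])
        dec = cwt(rec, wavelet)
        assert np.abs(dec.coeffs).max() == 0.0

    def test_unit_sinusoid_calibration_and_phase(self, sine_recording, wavelet):
        """A unit 10 Hz cosine yields interior modulus ~1 and a phase that
        advances at 2*pi*10 rad/s."""
        dec = cwt(sine_recording, wavelet)
        j = list(wavelet.freqs).index(10.0)
        interior = dec.valid_mask()[j]
        mod = np.abs(dec.coeffs[0, 0, j, interior])
        assert np.abs(mod - 1.0).max() < 0.02
        phase = np.unwrap(np.angle(dec.coeffs[0, 0, j, interior]))
        rate = np.diff(phase).mean() * 150.0 / (2 * np.pi)
        assert abs(rate - 10.0) < 0.01

    def test_modulus_peaks_at_stimulus_frequency(self, sine_recording, wavelet):
        dec = cwt(sine_recording, wavelet)
        mid = dec.coeffs.shape[-1] // 2
        peak_freq = dec.freqs[np.argmax(np.abs(dec.coeffs[0, 0, :, mid]))]
        assert peak_freq == 10.0

    def test_matches_direct_integration_on_small_epochs(self):
        # brute-force Riemann-sum oracle for the coefficient integral
        rng = np.random.default_rng(0)
        spec = WaveletSpec(freqs=(15.0, 25.0), srate=150.0)
        for seed in range(3):
            toy = np.random.default_rng(seed).standard_normal(64)
            rec = EpochedRecording(toy[None, None, :], 150.0, (-100.0, 320.0), ["rare"])
            dec = cwt(rec, spec)
            direct = cwt_direct(toy, spec, 150.0)
            assert np.abs(dec.coeffs[0, 0] - direct).max() < 1e-6

    def test_epoch_shorter_than_kernel_is_an_error(self):
        spec = WaveletSpec(freqs=(2.0,), srate=150.0)
        rec = EpochedRecording(np.zeros((1, 1, 31)), 150.0, (-100.0, 100.0), ["rare"])
        with pytest.raises(ValueError, match="shorter than"):
            cwt(rec, spec)

    def test_srate_mismatch_is_an_error(self, sine_recording):
        with pytest.raises(ValueError, match="srate"):
            cwt(sine_recording, WaveletSpec(freqs=(10.0,), srate=250.0))


class TestERP:
    def test_identical_trials_average_to_one_trial(self, wavelet):
        rng = np.random.default_rng(3)
        trial = rng.standard_normal((2, 451))
        rec = EpochedRecording(np.stack([trial] * 5), 150.0, (-1000.0, 2000.0),
                               ["rare"] * 5)
        fs = compute_erp(rec, range(5), BASE)
        from erpfuse.data_model import baseline_correct
        np.testing.assert_allclose(fs.tensor, baseline_correct(trial, rec.times, BASE))

    def test_opposite_trials_cancel(self):
        rng = np.random.default_rng(4)
        s = rng.standard_normal((1, 451))
        rec = EpochedRecording(np.stack([s, -s]), 150.0, (-1000.0, 2000.0),
                               ["rare", "rare"])
        fs = compute_erp(rec, [0, 1], BASE)
        np.testing.assert_allclose(fs.tensor, 0.0, atol=1e-12)

    def test_noise_suppression_scales_as_sqrt_n(self):
        """Averaging 24 trials of signal + sd-10 noise leaves ~10/sqrt(24) uV
        residual noise per sample (Monte-Carlo over cohorts)."""
        t = time_axis((-1000.0, 2000.0), 150.0)
        signal = 5.0 * np.exp(-((t - 300) ** 2) / (2 * 100.0**2))
        resid_sd = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data = signal[None, None, :] + rng.standard_normal((24, 1, 451)) * 10.0
            rec = EpochedRecording(data, 150.0, (-1000.0, 2000.0), ["rare"] * 24)
            fs = compute_erp(rec, range(24), BASE)
            expected = signal - signal[(t >= -200) & (t <= 0)].mean()
            resid_sd.append((fs.tensor[0] - expected).std())
        mean_resid = np.mean(resid_sd)
        assert 0.7 * 10 / np.sqrt(24) < mean_resid < 1.4 * 10 / np.sqrt(24)

    def test_empty_subset_is_an_error(self, noisy_recording):
        with pytest.raises(ValueError, match="non-empty"):
            compute_erp(noisy_recording, [], BASE)


def _decomposition_from(coeffs):
    return SpectralDecomposition(coeffs=coeffs, freqs=np.arange(coeffs.shape[2]) + 4.0,
                                 srate=150.0, window=(-1000.0, 2000.0))


class TestTFPower:
    def test_constant_modulus_baselines_to_zero(self):
        rng = np.random.default_rng(0)
        phases = rng.uniform(-np.pi, np.pi, (6, 2, 3, 451))
        dec = _decomposition_from(2.5 * np.exp(1j * phases))
        fs = tf_power(dec, range(6), BASE)
        np.testing.assert_allclose(fs.tensor, 0.0, atol=1e-12)
        raw = np.abs(dec.coeffs)
        np.testing.assert_allclose(raw, 2.5)

    def test_single_trial_mode_returns_one_sample_per_trial(self):
        rng = np.random.default_rng(1)
        dec = _decomposition_from(rng.standard_normal((4, 2, 3, 451))
                                  + 1j * rng.standard_normal((4, 2, 3, 451)))
        out = tf_power(dec, [0, 2], BASE, average=False)
        assert [fs.trial_ids for fs in out] == [(0,), (2,)]
        for fs in out:
            assert fs.kind == "tf_power"

    def test_gain_drop_appears_as_negative_baselined_power(self, wavelet):
        """A free-phase oscillation halved after onset shows baselined power
        ~ -0.5 x its pre-stimulus modulus at its own frequency."""
        from erpfuse.synthetic import SimulationConfig, SourceSpec, simulate_participant

        src = SourceSpec(kind="ongoing_oscillation", topography=(1.0,),
                         center_freq=10.0, amplitude_uv=4.0, phase_mode="free",
                         post_stimulus_gain=0.5, gain_ramp_ms=200.0)
        cfg = SimulationConfig(n_participants=1, n_rare=12, n_frequent=2,
                               n_channels=1, background_rms_uv=1e-9,
                               sources=((src, src),), seed=0)
        rec = simulate_participant(cfg, 0)
        dec = cwt(rec, wavelet)
        j = list(wavelet.freqs).index(10.0)
        fs = tf_power(dec, rec.trial_indices("rare"), BASE)
        t = rec.times
        post = (t > 600) & (t < 1500)
        np.testing.assert_allclose(fs.tensor[0, j, post], -0.5 * 4.0, rtol=0.05)


class TestTFPhase:
    def test_angle_conventions(self):
        coeffs = np.array([1.0, 1j, -1.0, -1j]).reshape(1, 1, 1, 4)
        coeffs = np.tile(coeffs, (1, 1, 3, 1))
        dec = _decomposition_from(coeffs)
        fs = tf_phase(dec, 0)
        np.testing.assert_allclose(fs.tensor[0, 0], [0.0, np.pi / 2, np.pi, -np.pi / 2])

    def test_values_in_half_open_interval(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal((2, 1, 3, 50)) + 1j * rng.standard_normal((2, 1, 3, 50))
        fs = tf_phase(_decomposition_from(z), 1)
        assert fs.tensor.max() <= np.pi and fs.tensor.min() > -np.pi

    def test_cos_sin_encoding_is_consistent_with_angle(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal((2, 1, 3, 50)) + 1j * rng.standard_normal((2, 1, 3, 50))
        dec = _decomposition_from(z)
        ang = tf_phase(dec, 0).tensor
        enc = tf_phase(dec, 0, encoding="cos_sin").tensor
        assert enc.shape == (2,) + ang.shape
        np.testing.assert_allclose(enc[0], np.cos(ang))
        np.testing.assert_allclose(np.hypot(enc[0], enc[1]), 1.0)


class TestPhaseSynchronization:
    def test_identical_phases_reach_the_maximum(self):
        # closed form: sqrt((0.9^2 + 9*0.1^2)/10) = 0.3
        stat = phase_sync_statistic(np.full((24, 5), 1.234), axis=0)
        np.testing.assert_allclose(stat, 0.3)

    def test_uniform_histogram_gives_zero(self):
        width = 2 * np.pi / 10
        phases = -np.pi + width * (np.repeat(np.arange(10), 2) + 0.5)
        np.testing.assert_allclose(phase_sync_statistic(phases[:, None], axis=0), 0.0)

    def test_mean_square_under_uniform_phases(self):
        """E[stat^2] = 10 * p(1-p)/n / 10 = 0.09/n; n = 24 gives 0.00375."""
        rng = np.random.default_rng(11)
        draws = rng.uniform(-np.pi, np.pi, (24, 100_000))
        mean_sq = (phase_sync_statistic(draws, axis=0) ** 2).mean()
        np.testing.assert_allclose(mean_sq, 0.09 / 24, rtol=0.02)

    def test_boundary_phase_lands_in_first_bin(self):
        assert phase_bin_index(np.array([-np.pi]))[0] == 0
        assert phase_bin_index(np.array([np.pi]))[0] == 9

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 40))
    def test_statistic_bounded_and_shift_invariant(self, seed, n):
        phases = np.random.default_rng(seed).uniform(-np.pi, np.pi, (n, 3))
        stat = phase_sync_statistic(phases, axis=0)
        assert np.all(stat >= 0.0) and np.all(stat <= 0.3 + 1e-12)
        # shifting all phases by a whole bin width leaves the histogram shape
        shifted = phases + 2 * np.pi / 10
        shifted = np.pi - np.mod(np.pi - shifted, 2 * np.pi)
        np.testing.assert_allclose(phase_sync_statistic(shifted, axis=0), stat,
                                   atol=1e-12)

    def test_maximum_iff_single_bin(self):
        two_bins = np.array([0.1, 0.1, 0.1, -3.0])
        assert phase_sync_statistic(two_bins[:, None], axis=0)[0] < 0.3

    def test_fewer_than_two_trials_is_an_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            phase_sync_statistic(np.zeros((1, 4)), axis=0)

    def test_full_pipeline_baselines_per_channel_and_frequency(self):
        rng = np.random.default_rng(5)
        z = np.exp(1j * rng.uniform(-np.pi, np.pi, (24, 2, 3, 451)))
        dec = _decomposition_from(z)
        fs = phase_synchronization(dec, range(24), BASE)
        t = dec.times
        base_mask = (t >= -200) & (t <= 0)
        np.testing.assert_allclose(fs.tensor[..., base_mask].mean(axis=-1), 0.0,
                                   atol=1e-12)


class TestFeatureSample:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown feature kind"):
            FeatureSample(kind="bandpower", tensor=np.zeros(3), label="rare")

    def test_nonfinite_tensor_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            FeatureSample(kind="erp", tensor=np.array([1.0, np.inf]), label="rare")

    def test_crop_tensor_window(self):
        t = time_axis((-1000.0, 2000.0), 150.0)
        x = np.arange(451.0)
        out = crop_tensor(x, t, (-500.0, 1500.0))
        assert out.size == 301
        assert out[0] == 75.0
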