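"""Spectral estimation, zero-phase filtering, gamma-event extraction and
phase-amplitude coupling measures."""

import numpy as np
import pytest

from ca3net.rhythms import (GAMMA_BAND, THETA_BAND, CFCResult, Spectrum,
                            band_peak, bandpass_zero_phase, cfc_analysis,
                            extract_gamma_spikes, modulation_index,
                            phase_of_peak_gamma, phase_profile, psd_multitaper,
                            theta_phase)

FS = 1000.0


def synth_cfc_lfp(duration_s=30.0, fs=FS, theta_hz=8.0, gamma_hz=35.3,
                  phase_lag=0.6, depth=1.0, kappa=6.0, noise=0.05, seed=0):
    """Theta carrier with gamma bursts locked ``phase_lag`` rad after the
    theta peak; von-Mises-shaped modulation with depth in [0, 1]. The
    gamma carrier is incommensurate with theta so event phases sample the
    cycle densely."""
    rng = np.random.default_rng(seed)
    t = np.arange(int(duration_s * fs)) / fs
    phase = 2 * np.pi * theta_hz * t
    theta = np.cos(phase)
    envelope = (1 - depth) + depth * np.exp(kappa * (np.cos(phase - phase_lag) - 1))
    gamma = 0.3 * envelope * np.cos(2 * np.pi * gamma_hz * t)
    return theta + gamma + noise * rng.standard_normal(len(t))


class TestMultitaperPsd:
    def test_single_tone_peak(self):
        t = np.arange(8000) / FS
        x = np.sin(2 * np.pi * 8.0 * t)
        spec = psd_multitaper(x - x.mean(), FS)
        assert spec.freqs[np.argmax(spec.power)] == pytest.approx(8.0, abs=1.0)

    def test_white_noise_has_no_band_peak(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(4000)
            spec = psd_multitaper(x - x.mean(), FS)
            if spec.power.max() > 5 * np.median(spec.power):
                hits += 1
        assert hits == 0

    def test_parseval(self, rng):
        x = rng.standard_normal(5000)
        x -= x.mean()
        spec = psd_multitaper(x, FS)
        df = spec.freqs[1] - spec.freqs[0]
        assert np.sum(spec.power) * df == pytest.approx(np.var(x), rel=0.05)

    def test_spectrum_invariants(self, rng):
        spec = psd_multitaper(rng.standard_normal(2000), FS)
        assert np.all(spec.power >= 0)
        assert np.all(np.diff(spec.freqs) > 0)
        assert spec.freqs[-1] == pytest.approx(FS / 2)


class TestBandPeak:
    def _two_tone_spectrum(self):
        t = np.arange(16000) / FS
        x = np.sin(2 * np.pi * 8 * t) + 0.5 * np.sin(2 * np.pi * 40 * t)
        return psd_multitaper(x - x.mean(), FS)

    def test_tone_in_gamma_band(self):
        t = np.arange(16000) / FS
        x = np.sin(2 * np.pi * 33.5 * t)
        peak = band_peak(psd_multitaper(x, FS), GAMMA_BAND)
        assert peak.freq == pytest.approx(33.5, abs=0.5)

    def test_two_tones_resolved_per_band(self):
        spec = self._two_tone_spectrum()
        assert band_peak(spec, THETA_BAND).freq == pytest.approx(8, abs=0.7)
        assert band_peak(spec, GAMMA_BAND).freq == pytest.approx(40, abs=0.7)

    def test_monotone_band_flags_edge(self):
        freqs = np.linspace(1, 100, 500)
        spectrum = Spectrum(freqs=freqs, power=freqs.copy())  # rising PSD
        peak = band_peak(spectrum, GAMMA_BAND)
        assert peak.at_edge
        assert peak.freq == pytest.approx(55.0, abs=0.3)

    def test_uncovered_band_rejected(self):
        spectrum = Spectrum(freqs=np.linspace(100, 200, 50),
                            power=np.ones(50))
        with pytest.raises(ValueError):
            band_peak(spectrum, THETA_BAND)


class TestZeroPhaseFilter:
    def test_passband_tone_unshifted(self):
        t = np.arange(10000) / FS
        x = np.sin(2 * np.pi * 8 * t)
        y = bandpass_zero_phase(x, FS, 6, 10)
        core = slice(2000, 8000)
        # project onto the quadrature pair: phase shift < 1 degree
        i_part = 2 * np.mean(y[core] * np.sin(2 * np.pi * 8 * t[core]))
        q_part = 2 * np.mean(y[core] * np.cos(2 * np.pi * 8 * t[core]))
        assert abs(np.degrees(np.arctan2(q_part, i_part))) < 1.0
        assert i_part > 0.8  # passband gain near unity

    def test_stopband_attenuation(self):
        t = np.arange(10000) / FS
        x = np.sin(2 * np.pi * 40 * t)
        y = bandpass_zero_phase(x, FS, 6, 10)
        atten_db = 20 * np.log10(np.abs(y[2000:8000]).max())
        assert atten_db < -20.0

    def test_impulse_response_symmetric(self):
        x = np.zeros(4001)
        x[2000] = 1.0
        y = bandpass_zero_phase(x, FS, 6, 10)
        np.testing.assert_allclose(y, y[::-1], atol=1e-4 * np.abs(y).max())

    def test_rejects_undersampled_input(self):
        with pytest.raises(ValueError):
            bandpass_zero_phase(np.zeros(100), 15.0, 6, 10)


class TestGammaSpikeExtraction:
    @staticmethod
    def _bump_train(width_ms, n=40, spacing_ms=200, fs=FS):
        t = np.arange(int(n * spacing_ms * fs / 1000)) / fs * 1000
        x = np.zeros_like(t)
        centers = np.arange(100, t[-1] - 100, spacing_ms)
        for c in centers:
            m = np.abs(t - c) < width_ms / 2
            x[m] += 0.5 * (1 + np.cos(2 * np.pi * (t[m] - c) / width_ms))
        return x, centers

    def test_gamma_width_bumps_all_detected(self):
        x, centers = self._bump_train(30.0)
        peaks = extract_gamma_spikes(x, FS)
        assert len(peaks) == len(centers)
        assert np.allclose(np.sort(peaks), centers, atol=5)

    def test_slow_bumps_rejected(self):
        x, _ = self._bump_train(100.0, spacing_ms=400)
        assert len(extract_gamma_spikes(x, FS)) == 0

    def test_events_cluster_at_coupled_phase(self):
        lfp = synth_cfc_lfp(duration_s=40.0, phase_lag=0.6, depth=1.0)
        events = extract_gamma_spikes(lfp, FS)
        assert len(events) > 100
        phases = theta_phase(lfp, FS)[events]
        mean_dir = np.angle(np.mean(np.exp(1j * phases)))
        assert abs(mean_dir - 0.6) < 0.15


class TestModulationIndex:
    def test_uniform_phases_give_zero(self):
        phases = np.linspace(-np.pi + 1e-6, np.pi - 1e-6, 100_000)
        assert modulation_index(phases) == pytest.approx(0.0, abs=1e-4)

    def test_single_bin_gives_one(self):
        phases = np.full(1000, 0.123)
        assert modulation_index(phases) == pytest.approx(1.0)

    def test_matches_direct_histogram_kl(self, rng):
        phases = rng.vonmises(0.8, 2.0, size=10_000)
        # independent oracle: explicit KL of the empirical 100-bin histogram
        hist, _ = np.histogram(phases, bins=np.linspace(-np.pi, np.pi, 101))
        p = hist / hist.sum()
        kl = sum(pi * np.log(pi * 100) for pi in p if pi > 0)
        assert modulation_index(phases) == pytest.approx(kl / np.log(100),
                                                         abs=1e-12)

    def test_uniform_surrogate_below_001(self, rng):
        phases = rng.uniform(-np.pi, np.pi, size=10_000)
        assert modulation_index(phases) < 0.01

    def test_empty_phases_rejected(self):
        with pytest.raises(ValueError):
            modulation_index(np.array([]))


class TestPhaseOfPeakGamma:
    def test_peak_at_theta_peak_bin(self):
        profile = np.ones(100)
        profile[50] = 5.0  # bin covering phase ~ +pi/100
        assert abs(phase_of_peak_gamma(profile / profile.sum())) < 2 * np.pi / 100

    def test_circular_shift_equivariance(self):
        profile = np.ones(100)
        profile[50] = 5.0
        base = phase_of_peak_gamma(profile)
        shifted = phase_of_peak_gamma(np.roll(profile, 10))
        assert shifted - base == pytest.approx(10 * 2 * np.pi / 100)


class TestEndToEndCfc:
    def test_phase_recovery_within_tenth_radian(self):
        lfp = synth_cfc_lfp(duration_s=60.0, phase_lag=0.6, depth=1.0)
        result = cfc_analysis(lfp, FS)
        assert result.n_events > 100
        assert result.peak_phase == pytest.approx(0.6, abs=0.1)
        assert 0.0 <= result.mi <= 1.0

    def test_mi_monotone_in_modulation_depth(self):
        mis = []
        for depth in (0.2, 0.6, 1.0):
            lfp = synth_cfc_lfp(duration_s=40.0, depth=depth, seed=3)
            mis.append(cfc_analysis(lfp, FS).mi)
        assert mis[0] < mis[1] < mis[2]

    def test_no_events_degenerates_gracefully(self):
        result = cfc_analysis(np.zeros(5000), FS)
        assert result.mi == 0.0
        assert result.n_events == 0
        assert np.isnan(result.peak_phase)
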