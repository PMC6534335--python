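"""Canonical source, delay mixing, and the attenuation closed form."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from wavemix import (
    CanonicalWaveParams,
    CompoundSignal,
    DelayMixingConfig,
    analytic_attenuation,
    canonical_waveform,
    compound_signal,
    delta_ct,
    extract_cycles,
    modulate_one_over_f,
    phasor_sum,
    sample_delays,
    two_source_delay_sweep,
)
from wavemix.envelopes import narrowband_envelope, envelope_correlation


class TestCanonicalWaveform:
    def test_value_at_origin(self, params):
        assert canonical_waveform(params, np.array([0.0]))[0] == pytest.approx(
            0.25 * np.sin(1.0), abs=1e-12
        )

    def test_periodicity(self, params):
        t = np.linspace(0.0, 0.3, 500)
        np.testing.assert_allclose(
            canonical_waveform(params, t + 1.0 / params.f),
            canonical_waveform(params, t),
            atol=1e-10,
        )

    def test_pure_sinusoid_limit_is_symmetric(self):
        p = CanonicalWaveParams(A2=0.0)
        t = np.arange(10_000) / 1000.0
        from wavemix import TimeSeries

        d = delta_ct(extract_cycles(TimeSeries(canonical_waveform(p, t), 1000.0)))
        assert abs(d.delta_ct) < 0.01


class TestSampleDelays:
    def test_zero_sigma_gives_zero_delays(self):
        cfg = DelayMixingConfig(n_sources=50, sigma=0.0, seed=1)
        assert np.all(sample_delays(cfg) == 0.0)

    def test_law_of_large_numbers(self):
        sigma, n = 0.010, 10_000
        d = sample_delays(DelayMixingConfig(n_sources=n, sigma=sigma, seed=2))
        assert abs(d.mean()) < 3 * sigma / np.sqrt(n)
        assert d.std() == pytest.approx(sigma, rel=0.05)

    def test_seed_determinism(self):
        cfg = DelayMixingConfig(n_sources=100, sigma=0.02, seed=9)
        np.testing.assert_array_equal(sample_delays(cfg), sample_delays(cfg))


class TestCompoundSignal:
    def test_zero_sigma_is_scaled_source(self, params):
        cfg = DelayMixingConfig(n_sources=20, sigma=0.0, seed=3, duration=2.0, rate=1000.0)
        comp = compound_signal(params, cfg)
        t = comp.signal.times
        np.testing.assert_allclose(
            comp.signal.samples, 20.0 * canonical_waveform(params, t), atol=1e-9
        )

    def test_two_source_quarter_period_lag_cancels_beta(self, params):
        """Lag of 25 ms: the 20 Hz component vanishes, 10 Hz keeps half power."""
        cfg = DelayMixingConfig(n_sources=2, sigma=0.0, seed=0, duration=2.0, rate=1000.0)
        comp = compound_signal(params, cfg, delays=np.array([0.0, 0.025]))
        ref = compound_signal(params, cfg, delays=np.array([0.0, 0.0]))
        spec = np.abs(np.fft.rfft(comp.signal.samples)) ** 2
        spec_ref = np.abs(np.fft.rfft(ref.signal.samples)) ** 2
        bin10, bin20 = 20, 40  # 2 s duration -> 0.5 Hz bins
        assert spec[bin20] / spec_ref[bin20] < 1e-6
        assert spec[bin10] / spec_ref[bin10] == pytest.approx(0.5, abs=1e-6)

    def test_two_source_half_period_lag_leaves_only_beta(self, params):
        cfg = DelayMixingConfig(n_sources=2, sigma=0.0, seed=0, duration=2.0, rate=1000.0)
        comp = compound_signal(params, cfg, delays=np.array([0.0, 0.050]))
        t = comp.signal.times
        expected = 2.0 * params.A2 * np.sin(
            4 * np.pi * params.f * t + params.psi - 2 * np.pi
        )
        np.testing.assert_allclose(comp.signal.samples, expected, atol=1e-9)

    def test_linearity_over_delay_lists(self, params):
        d1 = np.array([0.0, 0.01, -0.005])
        d2 = np.array([0.002, -0.02])
        mk = lambda d: compound_signal(
            params,
            DelayMixingConfig(n_sources=len(d), sigma=0.01, seed=5, duration=1.0, rate=1000.0),
            delays=d,
        ).signal.samples
        np.testing.assert_allclose(
            mk(np.concatenate([d1, d2])), mk(d1) + mk(d2), atol=1e-10
        )

    def test_delayed_source_spectrum_invariant(self, params):
        """A time shift changes only spectral phase, not power."""
        t = np.arange(4000) / 1000.0  # integer number of periods: exact DFT lines
        a = np.abs(np.fft.rfft(canonical_waveform(params, t)))
        b = np.abs(np.fft.rfft(canonical_waveform(params, t - 0.0137)))
        for freq_bin in (40, 80):  # 10 and 20 Hz at 4 s
            assert b[freq_bin] == pytest.approx(a[freq_bin], rel=1e-9)

    def test_save_load_roundtrip(self, params, tmp_path):
        cfg = DelayMixingConfig(n_sources=5, sigma=0.01, seed=4, duration=1.0, rate=500.0)
        comp = compound_signal(params, cfg)
        comp.save(tmp_path / "comp")
        back = CompoundSignal.load(tmp_path / "comp")
        np.testing.assert_array_equal(back.signal.samples, comp.signal.samples)
        np.testing.assert_array_equal(back.delays, comp.delays)
        assert back.config == cfg and back.params == params


class TestModulation:
    def test_envelope_recovered_from_modulated_source(self, params):
        from wavemix import TimeSeries

        t = np.arange(30_000) / 1000.0
        source = TimeSeries(canonical_waveform(params, t), 1000.0)
        modulated, env = modulate_one_over_f(source, seed=11)
        # recover the envelope the way it was built: analytic-signal
        # magnitude, low-passed below f/2
        from scipy.signal import butter, hilbert, sosfiltfilt

        mag = np.abs(hilbert(modulated.samples))
        sos = butter(4, params.f / 2.0, btype="lowpass", fs=1000.0, output="sos")
        measured = TimeSeries(np.clip(sosfiltfilt(sos, mag), 1e-6, None), 1000.0)
        rho = envelope_correlation(measured, TimeSeries(env, 1000.0))
        assert rho > 0.9

    def test_alpha_beta_envelopes_comodulated(self, params):
        from wavemix import TimeSeries

        t = np.arange(30_000) / 1000.0
        source = TimeSeries(canonical_waveform(params, t), 1000.0)
        modulated, _ = modulate_one_over_f(source, seed=12)
        ea = narrowband_envelope(modulated, params.f)
        eb = narrowband_envelope(modulated, 2 * params.f)
        assert envelope_correlation(ea, eb) > 0.9

    def test_envelope_positive_and_unit_mean(self, params):
        from wavemix import TimeSeries

        t = np.arange(20_000) / 1000.0
        source = TimeSeries(canonical_waveform(params, t), 1000.0)
        _, env = modulate_one_over_f(source, seed=13)
        assert np.all(env > 0)
        assert env.mean() == pytest.approx(1.0, abs=1e-9)


class TestAnalyticAttenuation:
    def test_zero_sigma(self):
        assert analytic_attenuation(0.0, 10.0) == 1.0

    @pytest.mark.parametrize("sigma,f", [(0.005, 10.0), (0.02, 7.0), (0.03, 10.0)])
    def test_harmonic_exponent_identity(self, sigma, f):
        assert analytic_attenuation(sigma, 2 * f) == pytest.approx(
            analytic_attenuation(sigma, f) ** 4, rel=1e-12
        )

    def test_monte_carlo_agreement(self):
        """Ensemble-mean coherent phasor matches the closed form."""
        rng = np.random.default_rng(21)
        for sigma in (0.005, 0.02):
            for f in (10.0, 20.0):
                vals = [
                    phasor_sum(rng.normal(0, sigma, 40), f).real / 40.0
                    for _ in range(400)
                ]
                se = np.std(vals, ddof=1) / np.sqrt(len(vals))
                assert abs(np.mean(vals) - analytic_attenuation(sigma, f)) < 3 * max(se, 1e-4)


class TestTwoSourceSweep:
    def test_closed_form_values(self, params):
        grid = np.array([0.0, 0.025, 0.050])
        out = two_source_delay_sweep(params, grid)
        np.testing.assert_allclose(out["alpha_power"], [1.0, 0.5, 0.0], atol=1e-12)
        np.testing.assert_allclose(out["beta_power"], [1.0, 0.0, 1.0], atol=1e-12)

    def test_matches_cosine_law_on_dense_grid(self, params):
        grid = np.linspace(0.0, 0.1, 41)
        out = two_source_delay_sweep(params, grid)
        np.testing.assert_allclose(
            out["alpha_power"], np.cos(np.pi * params.f * grid) ** 2, atol=1e-12
        )
        np.testing.assert_allclose(
            out["beta_power"], np.cos(2 * np.pi * params.f * grid) ** 2, atol=1e-12
        )

    def test_compound_delta_ct_magnitude_falls_with_sigma(self, params):
        """Ensemble trend: larger delay spread, more sinusoidal compound."""
        rng = np.random.default_rng(17)
        sig_col, dct_col = [], []
        for sigma in (0.0, 0.01, 0.02):
            for _ in range(10):
                cfg = DelayMixingConfig(
                    n_sources=40, sigma=sigma, seed=int(rng.integers(2**31)),
                    duration=2.0, rate=1000.0,
                )
                comp = compound_signal(params, cfg)
                sig_col.append(sigma)
                dct_col.append(abs(delta_ct(extract_cycles(comp.signal)).delta_ct))
        assert spearmanr(sig_col, dct_col).statistic < -0.5
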