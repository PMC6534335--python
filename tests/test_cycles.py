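"""Crest/trough cycle extraction and the ΔCT statistic."""

import numpy as np
import pytest
from scipy.optimize import brentq

from wavemix import (
    CanonicalWaveParams,
    NoCyclesError,
    TimeSeries,
    UndefinedStatisticError,
    amplitude_filter,
    canonical_waveform,
    compute_delta_ct,
    delta_ct,
    extract_cycles,
    upsample,
)
from wavemix.cycles import CycleCatalog
from wavemix.mixing import one_over_f_noise


def _oracle_durations(params: CanonicalWaveParams):
    """Crest/trough durations of the canonical waveform by dense root-finding."""
    period = 1.0 / params.f
    f = lambda t: canonical_waveform(params, np.array([t]))[0]
    ts = np.linspace(0.0, period, 200_001)
    v = canonical_waveform(params, ts)
    roots = [
        brentq(f, ts[i], ts[i + 1], xtol=1e-12)
        for i in range(len(ts) - 1)
        if v[i] * v[i + 1] < 0
    ]
    # wrap around one full period to pair each crossing with the next
    roots = np.array(roots)
    durations = {}
    for a, b in zip(roots, np.append(roots[1:], roots[0] + period)):
        kind = "crest" if f((a + b) / 2.0 % period) > 0 else "trough"
        durations[kind] = b - a
    return durations["crest"], durations["trough"]


class TestExtractCycles:
    def test_sine_cycles(self):
        t = np.arange(1000) / 1000.0
        cat = extract_cycles(TimeSeries(np.sin(2 * np.pi * 10.0 * t), 1000.0))
        # edge half-cycles are discarded, so counts are 9-10 each
        assert 9 <= cat.n_crests <= 10
        assert 9 <= cat.n_troughs <= 10
        np.testing.assert_allclose(cat.crest_periods, 0.050, atol=1e-3)
        np.testing.assert_allclose(cat.trough_periods, 0.050, atol=1e-3)
        np.testing.assert_allclose(cat.crest_amplitudes, 1.0, atol=0.01)
        np.testing.assert_allclose(cat.trough_amplitudes, 1.0, atol=0.01)

    def test_duty_cycle_durations(self, duty_cycle_30_70):
        cat = extract_cycles(duty_cycle_30_70)
        assert np.mean(cat.crest_periods) == pytest.approx(0.030, abs=0.002)
        assert np.mean(cat.trough_periods) == pytest.approx(0.070, abs=0.002)

    def test_canonical_waveform_matches_root_finding_oracle(self, mu_wave, params):
        tc_oracle, tt_oracle = _oracle_durations(params)
        cat = extract_cycles(mu_wave)
        assert abs(np.mean(cat.crest_periods) - tc_oracle) < 1e-3
        assert abs(np.mean(cat.trough_periods) - tt_oracle) < 1e-3

    def test_crossings_alternate_and_increase(self, mu_wave):
        cat = extract_cycles(mu_wave)
        assert np.all(np.diff(cat.crossing_times) > 0)
        assert abs(cat.n_crests - cat.n_troughs) <= 1

    def test_too_few_crossings_raise(self):
        flat = TimeSeries(np.linspace(1.0, 2.0, 100), 100.0)
        with pytest.raises(NoCyclesError):
            extract_cycles(flat)


class TestAmplitudeFilter:
    def test_brute_force_percentile_oracle(self):
        cat = CycleCatalog(
            crest_periods=[0.05] * 4,
            trough_periods=[0.05] * 4,
            crest_amplitudes=[1.0, 2.0, 3.0, 4.0],
            trough_amplitudes=[1.0, 2.0, 3.0, 4.0],
            crossing_times=np.arange(8) * 0.05,
            first_crossing_up=True,
        )
        out = amplitude_filter(cat, 50.0)
        pooled = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        threshold = np.percentile(pooled, 50.0)
        expected = np.sort(pooled[pooled >= threshold])[: out.n_crests * 2]
        assert np.all(out.crest_amplitudes >= threshold)
        assert np.all(out.trough_amplitudes >= threshold)
        assert out.n_crests == int(np.sum(np.array([1, 2, 3, 4.0]) >= threshold))

    def test_all_equal_amplitudes_retained(self):
        cat = CycleCatalog(
            crest_periods=[0.05] * 3,
            trough_periods=[0.05] * 3,
            crest_amplitudes=[2.0] * 3,
            trough_amplitudes=[2.0] * 3,
            crossing_times=np.arange(6) * 0.05,
            first_crossing_up=True,
        )
        out = amplitude_filter(cat, 50.0)
        assert out.n_crests == 3 and out.n_troughs == 3

    def test_percentile_zero_is_noop(self, sine_10hz):
        cat = extract_cycles(sine_10hz)
        out = amplitude_filter(cat, 0.0)
        assert out.n_crests == cat.n_crests and out.n_troughs == cat.n_troughs


class TestDeltaCT:
    def test_sine_is_symmetric(self, sine_10hz):
        assert abs(compute_delta_ct(sine_10hz).delta_ct) < 0.01

    def test_duty_cycle_value(self, duty_cycle_30_70):
        est = delta_ct(extract_cycles(duty_cycle_30_70))
        assert est.delta_ct == pytest.approx(-0.4, abs=0.02)

    def test_undefined_without_troughs(self):
        cat = CycleCatalog(
            crest_periods=[0.05],
            trough_periods=[],
            crest_amplitudes=[1.0],
            trough_amplitudes=[],
            crossing_times=[0.0, 0.05],
            first_crossing_up=True,
        )
        with pytest.raises(UndefinedStatisticError):
            delta_ct(cat)

    @pytest.mark.parametrize("signal_fixture", ["mu_wave", "duty_cycle_30_70"])
    def test_antisymmetry_under_negation(self, signal_fixture, request):
        sig = request.getfixturevalue(signal_fixture)
        d = delta_ct(extract_cycles(sig)).delta_ct
        d_neg = delta_ct(extract_cycles(sig.replace(-sig.samples))).delta_ct
        assert d_neg == pytest.approx(-d, abs=2.0 / sig.rate)

    def test_time_reversal_invariance(self, mu_wave):
        d = delta_ct(extract_cycles(mu_wave)).delta_ct
        d_rev = delta_ct(extract_cycles(mu_wave.replace(mu_wave.samples[::-1]))).delta_ct
        assert d_rev == pytest.approx(d, abs=2.0 / mu_wave.rate)

    @pytest.mark.parametrize("scale", [0.1, 3.0, 1e4])
    def test_scale_invariance(self, mu_wave, scale):
        d = delta_ct(extract_cycles(mu_wave)).delta_ct
        d_scaled = delta_ct(extract_cycles(mu_wave.replace(scale * mu_wave.samples))).delta_ct
        assert d_scaled == pytest.approx(d, abs=1e-9)

    def test_sampling_rate_robustness(self, params):
        """ΔCT from 250 Hz data upsampled to 1000 Hz matches a 10 kHz reference."""
        t_hi = np.arange(100_000) / 10_000.0
        ref = delta_ct(
            extract_cycles(TimeSeries(canonical_waveform(params, t_hi), 10_000.0))
        ).delta_ct
        t_lo = np.arange(2_500) / 250.0
        coarse = TimeSeries(canonical_waveform(params, t_lo), 250.0)
        d = delta_ct(extract_cycles(upsample(coarse, 1000.0))).delta_ct
        assert d == pytest.approx(ref, abs=0.01)


class TestNoiseSpread:
    def test_crest_period_spread_grows_with_noise(self, mu_wave):
        """The spread (IQR) of crest periods rises with the 1/f-noise level."""
        from scipy.stats import spearmanr

        from wavemix import bandpass

        levels = [0.0, 0.2, 0.4, 0.8]
        rng = np.random.default_rng(7)
        level_col, iqr_col = [], []
        for level in levels:
            for _ in range(8):
                noise = one_over_f_noise(mu_wave.n, mu_wave.rate, rng)
                noisy = mu_wave.replace(mu_wave.samples + level * noise)
                cat = extract_cycles(bandpass(noisy))
                tc = cat.crest_periods
                level_col.append(level)
                iqr_col.append(np.percentile(tc, 75) - np.percentile(tc, 25))
        rho = spearmanr(level_col, iqr_col).statistic
        assert rho > 0.5
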