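"""Spatio-spectral decomposition: band selection, fitting, broadband projection."""

import numpy as np
import pytest

from wavemix import (
    ChannelMismatchError,
    MultichannelRecording,
    NoPeakError,
    SSDModel,
    SyntheticConfig,
    apply_broadband,
    band_snr,
    compute_delta_ct,
    fit_one_over_f,
    fit_ssd,
    generate,
    select_alpha_band,
    welch_spectrum,
)
from wavemix.mixing import one_over_f_noise


def _tone_recording(freq_amps, n_channels=6, duration=30.0, rate=250.0, seed=0):
    """Channels carrying sinusoids at given (freq, amplitude) plus 1/f noise."""
    rng = np.random.default_rng(seed)
    n = int(duration * rate)
    t = np.arange(n) / rate
    base = sum(a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)) for f, a in freq_amps)
    data = np.stack(
        [base * rng.uniform(0.5, 1.5) + 0.7 * one_over_f_noise(n, rate, rng) for _ in range(n_channels)]
    )
    return MultichannelRecording(data, rate)


class TestSelectAlphaBand:
    def test_single_10hz_source(self):
        rec = _tone_recording([(10.0, 1.0)])
        assert select_alpha_band(rec) == (8.0, 12.0)

    def test_stronger_of_two_sources_wins(self):
        rec = _tone_recording([(9.0, 1.2), (11.0, 0.6)])
        lo, hi = select_alpha_band(rec)
        assert (lo + hi) / 2.0 == 9.0

    def test_pure_noise_raises(self):
        rng = np.random.default_rng(5)
        data = np.stack([one_over_f_noise(15_000, 250.0, rng) for _ in range(6)])
        with pytest.raises(NoPeakError):
            select_alpha_band(MultichannelRecording(data, 250.0))


class TestFitSSD:
    def test_recovers_mixing_pattern(self):
        ds = generate(SyntheticConfig(n_channels=8, seed=21))
        model = fit_ssd(ds.recording, (8.0, 12.0))
        corr = abs(np.corrcoef(model.patterns[:, 0], ds.mixing_matrix[:, 0])[0, 1])
        assert corr > 0.95

    def test_no_band_source_means_no_dominant_eigenvalue(self):
        rng = np.random.default_rng(3)
        data = np.stack([one_over_f_noise(15_000, 250.0, rng) for _ in range(8)])
        model = fit_ssd(MultichannelRecording(data, 250.0), (8.0, 12.0))
        assert model.eigenvalues[0] / model.eigenvalues[1] < 2.0

    def test_channel_permutation_equivariance(self):
        ds = generate(SyntheticConfig(n_channels=8, seed=22))
        rec = ds.recording
        perm = np.array([3, 1, 7, 0, 5, 2, 6, 4])
        rec_p = MultichannelRecording(
            rec.data[perm], rec.rate, tuple(rec.channel_names[i] for i in perm)
        )
        m = fit_ssd(rec, (8.0, 12.0))
        m_p = fit_ssd(rec_p, (8.0, 12.0))
        np.testing.assert_allclose(m_p.filters[:, 0], m.filters[perm, 0], atol=1e-6)

    def test_scale_invariance(self):
        ds = generate(SyntheticConfig(n_channels=8, seed=23))
        rec = ds.recording
        scaled = MultichannelRecording(7.5 * rec.data, rec.rate, rec.channel_names)
        d1 = compute_delta_ct(apply_broadband(fit_ssd(rec, (8, 12)), rec, 1)[0]).delta_ct
        d2 = compute_delta_ct(apply_broadband(fit_ssd(scaled, (8, 12)), scaled, 1)[0]).delta_ct
        assert d2 == pytest.approx(d1, abs=1e-6)

    def test_eigenvalues_descending_and_patterns_consistent(self):
        ds = generate(SyntheticConfig(seed=24))
        model = fit_ssd(ds.recording, (8.0, 12.0))
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        # A = Cs W (W^T Cs W)^-1  =>  W^T A = I
        gram = model.filters.T @ model.patterns
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-6)

    def test_agrees_with_mne_reference_implementation(self):
        """Independent cross-check against mne.decoding.SSD on the same data."""
        import mne
        from mne.decoding import SSD as MneSSD

        ds = generate(SyntheticConfig(seed=42))
        rec = ds.recording
        info = mne.create_info(list(rec.channel_names), rec.rate, "eeg")
        ref = MneSSD(
            info,
            filt_params_signal=dict(l_freq=8, h_freq=12, l_trans_bandwidth=1, h_trans_bandwidth=1),
            filt_params_noise=dict(l_freq=6, h_freq=14, l_trans_bandwidth=1, h_trans_bandwidth=1),
            reg="oas",
            n_components=3,
        )
        with mne.utils.use_log_level("error"):
            ref.fit(rec.data[np.newaxis])
        ours = fit_ssd(rec, (8.0, 12.0))
        corr = abs(np.corrcoef(ref.patterns_[0], ours.patterns[:, 0])[0, 1])
        assert corr > 0.95


class TestApplyBroadband:
    def test_component_keeps_both_harmonic_peaks(self):
        ds = generate(SyntheticConfig(seed=31))
        comp = apply_broadband(fit_ssd(ds.recording, (8, 12)), ds.recording, 1)[0]
        spec = welch_spectrum(comp)
        fit = fit_one_over_f(spec, exclude_bands=((8, 13), (16, 26)))
        assert band_snr(spec, fit, (8, 13)).snr_db > 5.0
        assert band_snr(spec, fit, (16, 26)).snr_db > 5.0

    def test_identity_mixing_returns_the_sensor(self):
        """If the source *is* a sensor, its component equals that sensor up to scale."""
        rng = np.random.default_rng(6)
        n, rate = 15_000, 250.0
        t = np.arange(n) / rate
        source = np.sin(2 * np.pi * 10 * t) + 0.25 * np.sin(4 * np.pi * 10 * t + 1.0)
        data = np.stack([source] + [one_over_f_noise(n, rate, rng) for _ in range(5)])
        rec = MultichannelRecording(data, rate)
        model = fit_ssd(rec, (8.0, 12.0))
        comp = apply_broadband(model, rec, 1)[0]
        c = np.corrcoef(comp.samples, source)[0, 1]
        assert abs(c) > 0.99

    def test_channel_mismatch_rejected(self):
        ds = generate(SyntheticConfig(seed=32))
        model = fit_ssd(ds.recording, (8.0, 12.0))
        other = MultichannelRecording(
            ds.recording.data[:6], ds.recording.rate, ds.recording.channel_names[:6]
        )
        with pytest.raises(ChannelMismatchError):
            apply_broadband(model, other)


class TestModelSerialization:
    def test_save_load_roundtrip(self, tmp_path):
        ds = generate(SyntheticConfig(seed=33))
        model = fit_ssd(ds.recording, (8.0, 12.0))
        model.save(tmp_path / "model")
        back = SSDModel.load(tmp_path / "model")
        np.testing.assert_array_equal(back.filters, model.filters)
        np.testing.assert_array_equal(back.patterns, model.patterns)
        assert back.band == model.band and back.flanks == model.flanks
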