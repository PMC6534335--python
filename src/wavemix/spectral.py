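"""Spectral estimation, aperiodic (1/f) correction, and alpha/beta ratios.

Power spectra are averaged modified periodograms (Hann window, 1 s
windows, 50% overlap), giving 1 Hz frequency resolution.  The aperiodic
background of EEG-like spectra is modelled as a low-order polynomial of
log-power versus log-frequency; oscillatory peaks are quantified as the
residual in dB above that fit ("SNR"), with the conventional inclusion
rule that a rhythm counts as present when its peak residual exceeds 5 dB.

The alpha/beta ratio of a segment is the raw Welch power at the alpha
peak frequency divided by the power at twice that frequency — raw, not
1/f-corrected, because the aperiodic fit is unstable on short segments.
A ratio below 1 means the beta harmonic momentarily dominates the base
rhythm, a signature of destructive interference at the base frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import welch

from .errors import NoPeakError, TooShortError, UnderdeterminedFitError
from .timeseries import TimeSeries

__all__ = [
    "PowerSpectrum",
    "AperiodicFit",
    "BandSNR",
    "RatioSeries",
    "welch_spectrum",
    "fit_one_over_f",
    "band_snr",
    "alpha_beta_ratio_over_segments",
    "fraction_ratio_below_one",
]

SNR_INCLUSION_DB = 5.0  # residual-peak threshold for "rhythm present"


@dataclass(frozen=True)
class PowerSpectrum:
    """Welch power spectral density with its estimation settings."""

    freqs: np.ndarray
    power: np.ndarray
    window: str = "hann"
    window_seconds: float = 1.0
    overlap: float = 0.5

    def __post_init__(self):
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        object.__setattr__(self, "power", np.asarray(self.power, dtype=float))
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have the same shape")
        if np.any(np.diff(self.freqs) <= 0) or np.any(self.freqs < 0):
            raise ValueError("freqs must be non-negative and increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    def power_at(self, freq_hz: float) -> float:
        """Power in the single bin nearest to ``freq_hz``."""
        return float(self.power[np.argmin(np.abs(self.freqs - freq_hz))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"freq_hz": self.freqs, "power": self.power})


@dataclass(frozen=True)
class AperiodicFit:
    """Polynomial 1/f model fit in log-log coordinates.

    ``coefficients`` are numpy polyfit coefficients (highest degree first)
    mapping log10(freq) to power in dB.  ``residual_db`` is the spectrum
    in dB minus the fitted background, defined over ``fit_freqs``.
    """

    coefficients: np.ndarray
    fit_domain: tuple[float, float]
    fit_freqs: np.ndarray
    residual_db: np.ndarray

    def model_db(self, freqs: np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients, np.log10(np.asarray(freqs, dtype=float)))

    def residual_at(self, freq_hz: float) -> float:
        return float(self.residual_db[np.argmin(np.abs(self.fit_freqs - freq_hz))])


@dataclass(frozen=True)
class BandSNR:
    """Residual-spectrum peak within a band: location and height in dB."""

    peak_freq: float
    snr_db: float
    band: tuple[float, float]

    def __post_init__(self):
        if not (self.band[0] <= self.peak_freq <= self.band[1]):
            raise ValueError("peak_freq must lie inside band")

    @property
    def includable(self) -> bool:
        """The conventional SNR > 5 dB inclusion criterion."""
        return self.snr_db > SNR_INCLUSION_DB


@dataclass(frozen=True)
class RatioSeries:
    """Per-segment alpha/beta power ratios; +inf marks zero beta power."""

    segment_length: float
    ratios: np.ndarray
    segment_starts: np.ndarray
    alpha_hz: float = 10.0

    def __post_init__(self):
        object.__setattr__(self, "ratios", np.asarray(self.ratios, dtype=float))
        object.__setattr__(self, "segment_starts", np.asarray(self.segment_starts, dtype=float))
        if self.ratios.shape != self.segment_starts.shape:
            raise ValueError("ratios and segment_starts must align")

    @property
    def n_infinite(self) -> int:
        return int(np.sum(np.isinf(self.ratios)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"segment_start_s": self.segment_starts, "alpha_beta_ratio": self.ratios}
        )


def welch_spectrum(
    signal: TimeSeries, window_seconds: float = 1.0, overlap: float = 0.5
) -> PowerSpectrum:
    """Averaged periodogram (Hann window, 1 s windows, 50% overlap).

    With 1 s windows the bin spacing is 1 Hz.  Density scaling, so
    sum(power) * df approximates the signal variance.
    """
    nperseg = int(round(window_seconds * signal.rate))
    if signal.n < nperseg:
        raise TooShortError(
            f"signal of {signal.n} samples shorter than one {window_seconds} s window"
        )
    freqs, power = welch(
        signal.samples,
        fs=signal.rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(nperseg * overlap),
        detrend="constant",
    )
    return PowerSpectrum(freqs, power, "hann", window_seconds, overlap)


def fit_one_over_f(
    spectrum: PowerSpectrum,
    exclude_bands: tuple[tuple[float, float], ...] = (),
    order: int = 2,
    fit_range: tuple[float, float] = (3.0, 40.0),
) -> AperiodicFit:
    """Fit the aperiodic background as a log-log polynomial.

    Oscillatory bands listed in ``exclude_bands`` are masked out of the
    fit so peaks do not drag the background up.  A quadratic in
    log10(f) captures the typical spectral knee without following
    narrowband structure.
    """
    f, p = spectrum.freqs, spectrum.power
    in_domain = (f >= fit_range[0]) & (f <= fit_range[1]) & (f > 0) & (p > 0)
    fit_mask = in_domain.copy()
    for lo, hi in exclude_bands:
        fit_mask &= ~((f >= lo) & (f <= hi))
    if fit_mask.sum() < order + 1:
        raise UnderdeterminedFitError(
            f"{int(fit_mask.sum())} fit points for {order + 1} coefficients"
        )
    logf = np.log10(f[fit_mask])
    db = 10.0 * np.log10(p[fit_mask])
    coeffs = np.polyfit(logf, db, order)
    fit_freqs = f[in_domain]
    residual = 10.0 * np.log10(p[in_domain]) - np.polyval(coeffs, np.log10(fit_freqs))
    return AperiodicFit(coeffs, fit_range, fit_freqs, residual)


def band_snr(
    spectrum: PowerSpectrum, fit: AperiodicFit, band: tuple[float, float]
) -> BandSNR:
    """Peak of the 1/f-corrected spectrum within a band, in dB."""
    mask = (fit.fit_freqs >= band[0]) & (fit.fit_freqs <= band[1])
    if not mask.any():
        raise NoPeakError(f"band {band} outside fitted domain {fit.fit_domain}")
    freqs = fit.fit_freqs[mask]
    residual = fit.residual_db[mask]
    k = int(np.argmax(residual))
    return BandSNR(peak_freq=float(freqs[k]), snr_db=float(residual[k]), band=band)


def alpha_beta_ratio_over_segments(
    signal: TimeSeries,
    alpha_peak_hz: float = 10.0,
    segment_length: float = 5.0,
) -> RatioSeries:
    """Raw alpha/beta power ratio per non-overlapping segment.

    Each segment is Welch-analysed (1 s Hann windows); the ratio is the
    power in the bin nearest ``alpha_peak_hz`` over the bin nearest
    ``2 * alpha_peak_hz``.  No 1/f correction (unstable on short
    segments).  Segments with exactly zero beta power yield +inf.
    """
    if segment_length < 1.0:
        raise ValueError("segment_length must be >= 1 s")
    seg_n = int(round(segment_length * signal.rate))
    n_segments = signal.n // seg_n
    if n_segments < 1:
        raise TooShortError("signal shorter than one segment")
    ratios, starts = [], []
    for k in range(n_segments):
        seg = TimeSeries(signal.samples[k * seg_n : (k + 1) * seg_n], signal.rate)
        spec = welch_spectrum(seg)
        pa = spec.power_at(alpha_peak_hz)
        pb = spec.power_at(2.0 * alpha_peak_hz)
        ratios.append(pa / pb if pb > 0 else np.inf)
        starts.append(k * seg_n / signal.rate)
    return RatioSeries(segment_length, np.array(ratios), np.array(starts), alpha_peak_hz)


def fraction_ratio_below_one(series: RatioSeries) -> float:
    """Fraction of segments whose ratio is strictly below 1.

    Infinite ratios (zero beta power) count toward the denominator — they
    are segments, and trivially not below 1.
    """
    if series.ratios.size == 0:
        raise ValueError("empty ratio series")
    finite = np.isfinite(series.ratios)
    return float(np.mean(finite & (series.ratios < 1.0)))
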