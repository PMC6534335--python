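"""Spatio-spectral decomposition (SSD) of multichannel recordings.

SSD extracts oscillatory components by maximizing power in a target band
relative to its flanking bands: with ``Cs`` the covariance of band-passed
data and ``Cn`` the covariance of flank-passed data, the spatial filters
``W`` solve the generalized eigenproblem ``Cs w = lambda Cn w``.  Sorted
by descending eigenvalue, the leading components are the most band-SNR-
dominant linear combinations of channels.  Activation patterns (the
forward-model columns, comparable to ground-truth mixing columns) are
``A = Cs W (W^T Cs W)^{-1}``.

The filters are trained on a narrow band (individual alpha peak +/- 2 Hz)
but applied to *broadband* data: if the base rhythm and its harmonic stem
from the same spatial source, the alpha-trained filter co-projects the
beta harmonic, and the component recovers the non-sinusoidal waveform
that mixing hides at the sensors.

Conventions: flanks are (lo-2, lo-1) and (hi+1, hi+2) Hz (order-2
Butterworth, covariances summed), leaving a 1 Hz transition gap; the
flank covariance is shrunk toward the scaled identity by 1e-6 of its
mean eigenvalue for numerical stability; each filter's sign is fixed so
its largest-magnitude pattern entry is positive (eigenvectors are
sign-indeterminate, waveform polarity is not).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

from .errors import ChannelMismatchError, NoPeakError
from .spectral import band_snr, fit_one_over_f, welch_spectrum
from .timeseries import MultichannelRecording, TimeSeries, bandpass_multichannel

__all__ = ["SSDModel", "select_alpha_band", "fit_ssd", "apply_broadband"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SSDModel:
    """Fitted SSD: filters (channels x components), patterns, eigenvalues."""

    filters: np.ndarray
    patterns: np.ndarray
    eigenvalues: np.ndarray
    band: tuple[float, float]
    flanks: tuple[tuple[float, float], tuple[float, float]]
    channel_names: tuple[str, ...]

    def __post_init__(self):
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")

    @property
    def n_components(self) -> int:
        return self.filters.shape[1]

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / "filters.npy", self.filters)
        np.save(directory / "patterns.npy", self.patterns)
        meta = {
            "eigenvalues": self.eigenvalues.tolist(),
            "band": list(self.band),
            "flanks": [list(f) for f in self.flanks],
            "channel_names": list(self.channel_names),
        }
        (directory / "ssd_model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "SSDModel":
        directory = Path(directory)
        meta = json.loads((directory / "ssd_model.json").read_text())
        return cls(
            filters=np.load(directory / "filters.npy"),
            patterns=np.load(directory / "patterns.npy"),
            eigenvalues=np.asarray(meta["eigenvalues"], dtype=float),
            band=tuple(meta["band"]),
            flanks=tuple(tuple(f) for f in meta["flanks"]),
            channel_names=tuple(meta["channel_names"]),
        )


def select_alpha_band(
    recording: MultichannelRecording,
    search_band: tuple[float, float] = (8.0, 13.0),
    halfwidth_hz: float = 2.0,
    min_peak_db: float = 1.0,
) -> tuple[float, float]:
    """Individual alpha-peak band: residual-spectrum peak +/- 2 Hz.

    The channel-average Welch spectrum is 1/f-corrected (alpha and its
    harmonic band masked from the fit); the peak of the residual within
    the search band defines the subject's alpha frequency.  Raises
    :class:`NoPeakError` if no residual peak rises above ``min_peak_db``
    (1 dB — the argmax of the residual over a few bins of pure 1/f noise
    sits well below that, a genuine rhythm well above).
    """
    spectra = [welch_spectrum(recording.channel(i)) for i in range(recording.n_channels)]
    mean_power = np.mean([s.power for s in spectra], axis=0)
    from .spectral import PowerSpectrum

    mean_spec = PowerSpectrum(spectra[0].freqs, mean_power)
    lo, hi = search_band
    fit = fit_one_over_f(mean_spec, exclude_bands=((lo, hi), (2 * lo, 2 * hi)))
    peak = band_snr(mean_spec, fit, search_band)
    if peak.snr_db <= min_peak_db:
        raise NoPeakError(
            f"no alpha peak above the 1/f background (best residual "
            f"{peak.snr_db:.2f} dB at {peak.peak_freq:g} Hz)"
        )
    return (peak.peak_freq - halfwidth_hz, peak.peak_freq + halfwidth_hz)


def _covariance(data: np.ndarray) -> np.ndarray:
    centered = data - data.mean(axis=1, keepdims=True)
    return centered @ centered.T / centered.shape[1]


def fit_ssd(
    recording: MultichannelRecording,
    band: tuple[float, float],
    filter_order: int = 2,
    shrinkage: float = 1e-6,
) -> SSDModel:
    """Fit SSD filters from band vs. flank covariances.

    Generalized eigendecomposition of (signal covariance, flank
    covariance); shrinkage regularization is escalated tenfold on failure
    (with a log message) before giving up.
    """
    lo, hi = band
    flanks = ((lo - 2.0, lo - 1.0), (hi + 1.0, hi + 2.0))
    band_data = bandpass_multichannel(recording, lo, hi, filter_order)
    cs = _covariance(band_data.data)
    cn = np.zeros_like(cs)
    for flo, fhi in flanks:
        flank_data = bandpass_multichannel(recording, flo, fhi, filter_order)
        cn += _covariance(flank_data.data)

    scale = np.trace(cn) / cn.shape[0]
    reg = shrinkage
    while True:
        try:
            eigvals, eigvecs = scipy.linalg.eigh(cs, cn + reg * scale * np.eye(cn.shape[0]))
            break
        except scipy.linalg.LinAlgError:
            if reg > 1e2:
                raise
            reg *= 10.0
            logger.warning("flank covariance singular; shrinkage raised to %g", reg)

    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    filters = eigvecs[:, order]
    patterns = cs @ filters @ np.linalg.inv(filters.T @ cs @ filters)
    # deterministic sign: largest-|.| pattern entry positive, per component
    for k in range(patterns.shape[1]):
        j = int(np.argmax(np.abs(patterns[:, k])))
        if patterns[j, k] < 0:
            patterns[:, k] *= -1.0
            filters[:, k] *= -1.0
    return SSDModel(
        filters=filters,
        patterns=patterns,
        eigenvalues=eigvals,
        band=(lo, hi),
        flanks=flanks,
        channel_names=recording.channel_names,
    )


def apply_broadband(
    model: SSDModel,
    recording: MultichannelRecording,
    n_components: int | None = 3,
) -> list[TimeSeries]:
    """Project broadband data through the alpha-trained spatial filters.

    Deliberately *no* narrowband re-filtering: harmonics that share the
    alpha source's spatial pattern ride through, which is exactly what
    makes the component's non-sinusoidal waveform recoverable.  Returns
    the top ``n_components`` component time courses (all if None).
    """
    if recording.channel_names != model.channel_names:
        raise ChannelMismatchError("recording channels differ from fit-time channels")
    k = model.n_components if n_components is None else min(n_components, model.n_components)
    comps = model.filters[:, :k].T @ recording.data
    return [
        TimeSeries(comps[i], recording.rate, label=f"ssd{i:02d}") for i in range(k)
    ]
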