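"""Uniformly sampled signals and the filtering/resampling primitives.

:class:`TimeSeries` is the carrier passed between every analysis stage:
a real-valued, uniformly sampled signal with its sampling rate.
:class:`MultichannelRecording` is the sensor-space analogue (channels x
samples).  Filtering is zero-phase (forward-backward) throughout, because
a causal filter's asymmetric phase response would itself distort
crest/trough durations and bias any waveform-shape statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfiltfilt

from .errors import ChannelMismatchError, InvalidBandError, TooShortError

__all__ = [
    "TimeSeries",
    "MultichannelRecording",
    "bandpass",
    "upsample",
    "design_bandpass",
]


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples
        Signal values (arbitrary units, e.g. microvolt).
    rate
        Sampling frequency in Hz, > 0.
    label
        Optional human-readable name carried through the pipeline.
    """

    samples: np.ndarray
    rate: float
    label: str | None = None

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if samples.size < 2:
            raise ValueError("need at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if not (self.rate > 0):
            raise ValueError("rate must be positive")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Time span from first to last sample, in seconds."""
        return (self.n - 1) / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.rate

    def replace(self, samples: np.ndarray, label: str | None = None) -> "TimeSeries":
        return TimeSeries(samples, self.rate, label if label is not None else self.label)


@dataclass(frozen=True)
class MultichannelRecording:
    """Sensor-space data: ``data`` is channels x samples."""

    data: np.ndarray
    rate: float
    channel_names: tuple[str, ...] = field(default=())

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2 or data.shape[0] < 2:
            raise ValueError("need a 2-D array with >= 2 channels")
        if not np.all(np.isfinite(data)):
            raise ValueError("data must be finite")
        if not (self.rate > 0):
            raise ValueError("rate must be positive")
        if not self.channel_names:
            names = tuple(f"ch{i:02d}" for i in range(data.shape[0]))
            object.__setattr__(self, "channel_names", names)
        elif len(self.channel_names) != data.shape[0]:
            raise ChannelMismatchError("channel_names length != number of channels")
        else:
            object.__setattr__(self, "channel_names", tuple(self.channel_names))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, index: int) -> TimeSeries:
        return TimeSeries(self.data[index], self.rate, label=self.channel_names[index])


def design_bandpass(low_hz: float, high_hz: float, order: int, rate: float):
    """Butterworth band-pass in second-order sections.

    Raises :class:`InvalidBandError` if the band is empty or extends to or
    beyond the Nyquist frequency.
    """
    nyq = rate / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise InvalidBandError(
            f"band ({low_hz}, {high_hz}) Hz invalid for rate {rate} Hz (Nyquist {nyq} Hz)"
        )
    if order < 1:
        raise ValueError("order must be >= 1")
    return butter(order, [low_hz, high_hz], btype="bandpass", fs=rate, output="sos")


def _sosfiltfilt_checked(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    # default filtfilt padding; signal must exceed it
    ntaps = 2 * sos.shape[0] + 1
    padlen = 3 * ntaps
    if x.shape[-1] <= padlen:
        raise TooShortError(
            f"signal of {x.shape[-1]} samples too short for zero-phase filtering "
            f"(needs > {padlen})"
        )
    return sosfiltfilt(sos, x, axis=-1)


def bandpass(
    signal: TimeSeries,
    low_hz: float = 3.0,
    high_hz: float = 45.0,
    order: int = 4,
) -> TimeSeries:
    """Zero-phase Butterworth band-pass filter.

    Defaults (3-45 Hz, order 4) are the standard preprocessing for the
    crest/trough-difference statistic: wide enough to keep the alpha rhythm
    together with its beta harmonic (whose relative phase carries the
    waveform asymmetry), while removing slow drifts that would displace
    zero-crossings.
    """
    sos = design_bandpass(low_hz, high_hz, order, signal.rate)
    return signal.replace(_sosfiltfilt_checked(sos, signal.samples))


def bandpass_multichannel(
    recording: MultichannelRecording,
    low_hz: float,
    high_hz: float,
    order: int,
) -> MultichannelRecording:
    """Zero-phase band-pass applied to every channel of a recording."""
    sos = design_bandpass(low_hz, high_hz, order, recording.rate)
    return MultichannelRecording(
        _sosfiltfilt_checked(sos, recording.data), recording.rate, recording.channel_names
    )


def upsample(signal: TimeSeries, target_rate: float) -> TimeSeries:
    """Cubic-spline interpolation to a higher sampling rate.

    The output grid spans the same time interval; whenever an output
    instant coincides with an input instant the original value is
    reproduced exactly (the spline interpolates its knots).  Intended to
    raise e.g. 250 Hz EEG to 1000 Hz for millisecond-precision
    zero-crossing timing.  Downsampling is refused.
    """
    if target_rate < signal.rate:
        raise ValueError(
            f"downsampling not supported (have {signal.rate} Hz, asked {target_rate} Hz)"
        )
    if target_rate == signal.rate:
        return signal
    spline = CubicSpline(signal.times, signal.samples)
    n_out = int(round(signal.duration * target_rate)) + 1
    t_out = np.arange(n_out) / target_rate
    # guard against float round-up past the last knot
    t_out = t_out[t_out <= signal.duration + 1e-12]
    return TimeSeries(spline(t_out), target_rate, signal.label)
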