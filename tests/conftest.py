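"""Shared fixtures: small deterministic signals used across the suite."""

import numpy as np
import pytest
from scipy.signal import sosfiltfilt, butter

from wavemix import CanonicalWaveParams, TimeSeries, canonical_waveform


@pytest.fixture
def params():
    return CanonicalWaveParams()


@pytest.fixture
def sine_10hz():
    """10 Hz unit sinusoid, 10 s at 1000 Hz."""
    t = np.arange(10_000) / 1000.0
    return TimeSeries(np.sin(2 * np.pi * 10.0 * t), 1000.0, label="sine10")


@pytest.fixture
def mu_wave(params):
    """Canonical two-harmonic waveform, 10 s at 1000 Hz."""
    t = np.arange(10_000) / 1000.0
    return TimeSeries(canonical_waveform(params, t), 1000.0, label="mu")


@pytest.fixture
def duty_cycle_30_70():
    """Rectangular 30 ms positive / 70 ms negative wave with smoothed edges.

    Smoothing (a 40 Hz low-pass) rounds the corners without moving the
    zero-crossings: the waveform stays antisymmetric about its crossings
    on each edge, so mean crest/trough durations remain 30/70 ms.
    """
    rate = 1000.0
    period = np.concatenate([np.ones(30), -np.ones(70)])
    x = np.tile(period, 100)  # 10 s
    sos = butter(4, 40.0, btype="lowpass", fs=rate, output="sos")
    return TimeSeries(sosfiltfilt(sos, x), rate, label="duty30/70")
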