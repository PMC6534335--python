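"""Minimal EDF (European Data Format) writer for multichannel recordings.

EDF stores signals as 16-bit integers with a per-channel linear physical
calibration, in fixed-duration data records after a plain-ASCII header.
This writer emits standard EDF with 1-second records, enough for
round-tripping a recording through any EDF reader (re-import in tests
uses :func:`mne.io.read_raw_edf`).  Amplitude error of a round-trip is
bounded by the 16-bit quantization step (phys range / 65535).

Only integer sampling rates are supported (one record per second), and
the recording is truncated to a whole number of records.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .timeseries import MultichannelRecording

__all__ = ["write_edf", "read_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: MultichannelRecording, path) -> None:
    """Write a recording to ``path`` as EDF (16-bit, 1 s data records)."""
    rate = recording.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(rate))  # samples per record per signal
    n_records = recording.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one 1 s EDF record")
    ns = recording.n_channels
    data = recording.data[:, : n_records * spr]

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    # avoid a degenerate calibration for constant channels
    flat = phys_max - phys_min < 1e-12
    phys_min = np.where(flat, phys_min - 1.0, phys_min)
    phys_max = np.where(flat, phys_max + 1.0, phys_max)

    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate X X X X", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(256 * (ns + 1)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),
            _field(str(ns), 4),
        ]
    )
    labels = b"".join(_field(name, 16) for name in recording.channel_names)
    transducer = b"".join(_field("", 80) for _ in range(ns))
    phys_dim = b"".join(_field("uV", 8) for _ in range(ns))
    pmin = b"".join(_field(f"{v:.8g}"[:8], 8) for v in phys_min)
    pmax = b"".join(_field(f"{v:.8g}"[:8], 8) for v in phys_max)
    dmin = b"".join(_field(str(_DIG_MIN), 8) for _ in range(ns))
    dmax = b"".join(_field(str(_DIG_MAX), 8) for _ in range(ns))
    prefilter = b"".join(_field("", 80) for _ in range(ns))
    spr_f = b"".join(_field(str(spr), 8) for _ in range(ns))
    reserved = b"".join(_field("", 32) for _ in range(ns))

    # headers round phys min/max to 8 ASCII chars; calibrate against the
    # *written* values so the reader's reconstruction matches
    pmin_written = np.array([float(pmin[i * 8 : (i + 1) * 8]) for i in range(ns)])
    pmax_written = np.array([float(pmax[i * 8 : (i + 1) * 8]) for i in range(ns)])
    gain = (_DIG_MAX - _DIG_MIN) / (pmax_written - pmin_written)
    digital = np.rint(
        (data - pmin_written[:, None]) * gain[:, None] + _DIG_MIN
    ).astype("<i2")
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(Path(path), "wb") as fh:
        fh.write(header + labels + transducer + phys_dim + pmin + pmax + dmin + dmax)
        fh.write(prefilter + spr_f + reserved)
        for r in range(n_records):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def read_edf(path) -> MultichannelRecording:
    """Read an EDF file back into a recording (via mne)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts for uV-dimensioned channels
    return MultichannelRecording(data, raw.info["sfreq"], tuple(raw.ch_names))
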