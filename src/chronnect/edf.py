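"""Minimal 16-bit EDF writer.

Writes a standard EDF header (256 bytes + 256 per signal) followed by
little-endian int16 data records, scaling each channel to its own
physical min/max.  Reading goes through :func:`chronnect.preprocess.read_recording`
(mne's EDF reader); this writer exists so synthetic recordings can be
round-tripped through the same on-disk format real cohorts use.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

__all__ = ["write_edf"]


def _field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, data: np.ndarray, fs: float, labels=None) -> None:
    """Write ``data`` (n_channels x n_samples, microvolts) as a 16-bit EDF file.

    The record duration is chosen as 1 s (fs samples per record); a trailing
    partial second is zero-padded.  fs must be a positive integer.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (channels x samples)")
    fs_i = int(round(fs))
    if fs_i != fs or fs_i <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch, n_samp = data.shape
    if labels is None:
        labels = [f"EEG {i:03d}" for i in range(n_ch)]
    if len(labels) != n_ch:
        raise ValueError("labels length must equal channel count")

    n_rec = int(np.ceil(n_samp / fs_i))
    padded = np.zeros((n_ch, n_rec * fs_i))
    padded[:, :n_samp] = data

    phys_min = np.floor(padded.min(axis=1))
    phys_max = np.ceil(padded.max(axis=1))
    same = phys_max <= phys_min
    phys_max[same] = phys_min[same] + 1.0
    dig_min, dig_max = -32768, 32767

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),  # patient id
            _field("Startdate 01-JAN-2000 X X X", 80),  # recording id
            _field(now.strftime("%d.%m.%y"), 8),
            _field(now.strftime("%H.%M.%S"), 8),
            _field(str(256 * (1 + n_ch)), 8),
            _field("", 44),
            _field(str(n_rec), 8),
            _field("1", 8),  # record duration, seconds
            _field(str(n_ch), 4),
        ]
    )
    header += b"".join(_field(lab, 16) for lab in labels)
    header += b"".join(_field("", 80) for _ in range(n_ch))  # transducer
    header += b"".join(_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_field(f"{v:g}"[:8], 8) for v in phys_min)
    header += b"".join(_field(f"{v:g}"[:8], 8) for v in phys_max)
    header += b"".join(_field(str(dig_min), 8) for _ in range(n_ch))
    header += b"".join(_field(str(dig_max), 8) for _ in range(n_ch))
    header += b"".join(_field("", 80) for _ in range(n_ch))  # prefiltering
    header += b"".join(_field(str(fs_i), 8) for _ in range(n_ch))
    header += b"".join(_field("", 32) for _ in range(n_ch))

    # digitize per channel against the *floored/ceiled* physical range so the
    # reader's scaling reproduces values to better than half a digital unit
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((padded - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            chunk = digital[:, r * fs_i : (r + 1) * fs_i]
            fh.write(chunk.tobytes())
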