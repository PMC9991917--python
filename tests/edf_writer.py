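"""Minimal EDF writer used as an independent oracle for the EDF reader.

Writes a valid EDF (not EDF+) file: 256-byte fixed header, 256 bytes per
signal, then 16-bit little-endian data records.  Only what a read-back test
needs — integer-second records, one physical-unit scaling per channel.
"""

from __future__ import annotations

import numpy as np


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} wider than {width}")
    return s.ljust(width).encode("ascii")


def write_edf(path, data: np.ndarray, fs: float, channel_ids=None,
              phys_range: float = 1000.0) -> None:
    """Write ``data`` (n_channels, n_samples; physical units, e.g. uV).

    ``fs`` must be a positive integer; the file holds one-second records.
    Samples are quantized to the int16 digital range over +-``phys_range``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_ch, n = data.shape
    fs = int(fs)
    n_rec = n // fs
    if n_rec * fs != n:
        raise ValueError("n_samples must be a whole number of 1-s records")
    if channel_ids is None:
        channel_ids = [f"ch{i}" for i in range(n_ch)]
    dig_min, dig_max = -32768, 32767
    phys_min, phys_max = -phys_range, phys_range

    header = b"".join([
        _field(0, 8),
        _field("synthetic", 80),
        _field("synthetic oracle file", 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(256 * (n_ch + 1), 8),
        _field("", 44),
        _field(n_rec, 8),
        _field(1, 8),
        _field(n_ch, 4),
    ])
    per_signal = [
        b"".join(_field(cid, 16) for cid in channel_ids),
        b"".join(_field("AgAgCl electrode", 80) for _ in range(n_ch)),
        b"".join(_field("uV", 8) for _ in range(n_ch)),
        b"".join(_field(phys_min, 8) for _ in range(n_ch)),
        b"".join(_field(phys_max, 8) for _ in range(n_ch)),
        b"".join(_field(dig_min, 8) for _ in range(n_ch)),
        b"".join(_field(dig_max, 8) for _ in range(n_ch)),
        b"".join(_field("", 80) for _ in range(n_ch)),
        b"".join(_field(fs, 8) for _ in range(n_ch)),
        b"".join(_field("", 32) for _ in range(n_ch)),
    ]
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.round((data - phys_min) * scale + dig_min), dig_min, dig_max
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for block in per_signal:
            fh.write(block)
        for r in range(n_rec):
            for c in range(n_ch):
                fh.write(digital[c, r * fs: (r + 1) * fs].tobytes())
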