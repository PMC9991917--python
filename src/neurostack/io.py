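"""File I/O: raw float32 + JSON sidecar container, EDF reading, event tables.

The on-disk raw container is little-endian IEEE-754 float32, channel
interleaved (sample 0 of every channel, then sample 1, ...), with a JSON
sidecar ``<stem>.json`` declaring ``{fs, n_channels, channel_ids, unit, t0}``.
Round-trips are bit-exact for float32 data.  EDF files are read through MNE
(exact to the format's 16-bit quantization).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CoreError, Event, EventStream, Recording


class IOError_(CoreError):
    """Base I/O error."""


class MissingSidecarError(IOError_):
    pass


class ChannelLengthError(IOError_):
    pass


class UnsupportedFormatError(IOError_):
    pass


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path) -> Path:
    """Write a Recording as raw_f32 + JSON sidecar; returns the data path."""
    path = Path(path)
    meta = {
        "fs": rec.fs,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "channel_ids": list(rec.channel_ids),
        "unit": rec.units,
        "t0": rec.t0,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    # channel-interleaved: frame-major order == Fortran order of (ch, t)
    rec.data.astype("<f4").T.tofile(path)
    return path


def read_recording(path, format: str = "raw_f32+json") -> Recording:
    """Read a recording from disk.

    ``format`` is ``raw_f32+json`` (default) or ``edf``.  Distinct error
    kinds: :class:`MissingSidecarError`, :class:`ChannelLengthError`,
    :class:`UnsupportedFormatError`.
    """
    path = Path(path)
    if format == "raw_f32+json":
        return _read_raw_f32(path)
    if format == "edf":
        return read_edf(path)
    raise UnsupportedFormatError(f"unsupported format {format!r}")


def _read_raw_f32(path: Path) -> Recording:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MissingSidecarError(f"no sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    raw = np.fromfile(path, dtype="<f4")
    n_ch = int(meta["n_channels"])
    if raw.size % n_ch != 0 or (
        "n_samples" in meta and raw.size != n_ch * int(meta["n_samples"])
    ):
        raise ChannelLengthError(
            f"{raw.size} float32 samples do not form {n_ch} equal-length channels"
        )
    data = raw.reshape(-1, n_ch).T.astype(np.float64)
    return Recording(
        data=data,
        fs=float(meta["fs"]),
        channel_ids=list(meta["channel_ids"]),
        t0=float(meta.get("t0", 0.0)),
        units=meta.get("unit", "uV"),
    )


def read_edf(path) -> Recording:
    """Read an EDF file (16-bit quantized) into a Recording."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()  # volts
    return Recording(
        data=data * 1e6,  # to microvolts
        fs=float(raw.info["sfreq"]),
        channel_ids=list(raw.ch_names),
        t0=0.0,
        units="uV",
    )


def write_events(events: EventStream, path) -> Path:
    """Write events as CSV with header (time_s, kind, label columns)."""
    path = Path(path)
    rows = []
    for e in events:
        row = {"time_s": e.time_s, "kind": e.kind}
        row.update(e.payload)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_events(path) -> EventStream:
    df = pd.read_csv(path)
    if "time_s" not in df.columns or "kind" not in df.columns:
        raise IOError_("event table needs time_s and kind columns")
    events = []
    extra = [c for c in df.columns if c not in ("time_s", "kind")]
    for _, row in df.iterrows():
        payload = {}
        for c in extra:
            v = row[c]
            if pd.notna(v):
                payload[c] = bool(v) if isinstance(v, (bool, np.bool_)) else v
        events.append(Event(float(row["time_s"]), str(row["kind"]), payload))
    return EventStream(events)
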