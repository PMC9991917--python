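"""Core domain types and shared signal primitives.

Multi-channel extracellular recordings are represented as a :class:`Recording`
(channels x samples, microvolts internally), behavioural/task markers as an
:class:`EventStream`, and filter requests as a :class:`FilterSpec`.  The
filtering, resampling and normalization helpers here are shared by every
downstream analysis stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
from scipy import signal


class CoreError(ValueError):
    """Base class for errors raised by the core primitives."""


class ConstantChannelError(CoreError):
    """A channel with zero variance was passed where variance is required."""


class FilterDesignError(CoreError):
    """Invalid filter specification for the recording's sampling rate."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Multi-channel time series.

    Parameters
    ----------
    data:
        Array of shape ``(n_channels, n_samples)``.  Amplitude unit is
        declared in ``units`` (microvolts internally, by convention).
    fs:
        Sampling rate in Hz; must be positive.
    channel_ids:
        Ordered, unique channel labels.
    t0:
        Recording start time in seconds.
    units:
        Declared amplitude unit (default microvolts).
    """

    data: np.ndarray
    fs: float
    channel_ids: Sequence[str]
    t0: float = 0.0
    units: str = "uV"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.fs <= 0:
            raise CoreError(f"sampling rate must be positive, got {self.fs}")
        self.channel_ids = list(self.channel_ids)
        if len(self.channel_ids) != self.data.shape[0]:
            raise CoreError(
                f"{len(self.channel_ids)} channel ids for "
                f"{self.data.shape[0]} data channels"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise CoreError("channel ids must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds (0-based indexing, offset by ``t0``)."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, channel_id: str) -> np.ndarray:
        return self.data[self.channel_ids.index(channel_id)]

    def copy_with(self, data: np.ndarray, fs: float | None = None) -> "Recording":
        return Recording(
            data=np.asarray(data, dtype=np.float64),
            fs=self.fs if fs is None else fs,
            channel_ids=list(self.channel_ids),
            t0=self.t0,
            units=self.units,
        )


EVENT_KINDS = {"word_onset", "crossing_start", "crossing_end", "trigger", "led_sync"}


@dataclass
class Event:
    time_s: float
    kind: str
    payload: dict = field(default_factory=dict)


@dataclass
class EventStream:
    """Time-stamped, typed task events (word onsets, crossings, triggers)."""

    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [e.time_s for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise CoreError("event times must be non-decreasing")
        for e in self.events:
            if e.kind not in EVENT_KINDS:
                raise CoreError(f"unknown event kind {e.kind!r}")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def of_kind(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.kind == kind]

    def times_of(self, kind: str) -> np.ndarray:
        return np.array([e.time_s for e in self.events if e.kind == kind])


@dataclass
class FilterSpec:
    """Named filter request: highpass/bandpass/notch with cutoffs in Hz."""

    kind: str
    cutoffs: tuple
    order: int = 4
    design: str = "butter"
    q: float = 30.0  # notch quality factor

    def __post_init__(self) -> None:
        if self.kind not in {"highpass", "bandpass", "lowpass", "notch"}:
            raise FilterDesignError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise FilterDesignError("filter order must be >= 1")
        cutoffs = tuple(np.atleast_1d(self.cutoffs).astype(float))
        if self.kind == "bandpass" and len(cutoffs) != 2:
            raise FilterDesignError("bandpass needs (low, high) cutoffs")
        if self.kind in {"highpass", "lowpass", "notch"} and len(cutoffs) != 1:
            raise FilterDesignError(f"{self.kind} needs a single cutoff")
        if any(c <= 0 for c in cutoffs):
            raise FilterDesignError("cutoffs must be positive")
        self.cutoffs = cutoffs

    def validate_for(self, fs: float) -> None:
        nyq = fs / 2.0
        if any(c >= nyq for c in self.cutoffs):
            raise FilterDesignError(
                f"cutoff(s) {self.cutoffs} not inside (0, {nyq}) for fs={fs}"
            )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def design_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    """Second-order-sections for a FilterSpec at sampling rate ``fs``.

    Butterworth for high/low/bandpass; 2nd-order IIR notch (Q=30 default).
    """
    spec.validate_for(fs)
    if spec.kind == "notch":
        b, a = signal.iirnotch(spec.cutoffs[0], spec.q, fs=fs)
        return signal.tf2sos(b, a)
    btype = {"highpass": "highpass", "lowpass": "lowpass", "bandpass": "bandpass"}[
        spec.kind
    ]
    wn = spec.cutoffs if spec.kind == "bandpass" else spec.cutoffs[0]
    return signal.butter(spec.order, wn, btype=btype, fs=fs, output="sos")


def filter_array(
    x: np.ndarray, spec: FilterSpec, fs: float, zero_phase: bool = True
) -> np.ndarray:
    """Filter along the last axis.  Zero-phase uses forward-backward passes."""
    sos = design_sos(spec, fs)
    if zero_phase:
        return signal.sosfiltfilt(sos, x, axis=-1)
    return signal.sosfilt(sos, x, axis=-1)


def apply_filter(rec: Recording, spec: FilterSpec, zero_phase: bool = True) -> Recording:
    """Apply a filter to every channel; shape and sampling rate preserved.

    Zero-phase (forward-backward) filtering is the default for analysis
    stages; causal single-pass filtering is available for real-time-style
    simulation where future samples must not be used.
    """
    return rec.copy_with(filter_array(rec.data, spec, rec.fs, zero_phase))


def resample(rec: Recording, target_fs: float) -> Recording:
    """Polyphase resampling with anti-alias filtering on downsampling.

    Output length is ``round(n_samples * target_fs / fs)`` for rational
    rate ratios (e.g. 38,600 Hz -> 386 Hz gives exactly 1/100 the samples).
    """
    if target_fs <= 0:
        raise CoreError("target_fs must be positive")
    if math.isclose(target_fs, rec.fs):
        return rec.copy_with(rec.data.copy())
    frac = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(rec.data, up, down, axis=-1)
    return rec.copy_with(out, fs=rec.fs * up / down)


def zscore_array(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise ConstantChannelError("cannot z-score a constant series")
    return (x - mu) / sd


def zscore(rec: Recording, per_channel: bool = True) -> Recording:
    """Normalize to zero mean, unit variance (each channel separately).

    Raises :class:`ConstantChannelError` naming the offending channel if a
    channel has zero variance.
    """
    if per_channel:
        sd = rec.data.std(axis=-1)
        bad = np.where(sd == 0)[0]
        if bad.size:
            names = [rec.channel_ids[i] for i in bad]
            raise ConstantChannelError(f"constant channel(s): {names}")
        out = (rec.data - rec.data.mean(axis=-1, keepdims=True)) / sd[:, None]
    else:
        sd = rec.data.std()
        if sd == 0:
            raise ConstantChannelError("constant recording")
        out = (rec.data - rec.data.mean()) / sd
    return rec.copy_with(out)


def robust_noise_sd(x: np.ndarray) -> float:
    """Robust noise SD estimate: median(|x|)/0.6745 (spike-immune)."""
    return float(np.median(np.abs(x)) / 0.6745)
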