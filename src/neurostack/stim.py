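"""Stimulation-burst programming and artifact-propagation statistics.

A :class:`StimProtocol` describes a grid of burst parameters the way the
stimulation engine is programmed: every (amplitude x frequency) combination
repeated ``repeats`` times (the propagation-mapping protocol is 5 x 5 x 4 =
100 bursts of 10 biphasic rectangular pulses, pulse width 1.28 ms,
interphase 150 us, interburst delay 16.67 s).  Propagated pulses are
detected in recordings by normalized cross-correlation against the rendered
pulse template, aligned at the correlation peak, and their power (sum of
squared samples over the aligned snippet) is normalized by the single
largest propagated pulse across all channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .core import CoreError, Recording


class ProtocolGridError(CoreError):
    """A protocol parameter is off the device grid."""


PULSE_WIDTH_RANGE_MS = (0.01, 1.28)
PULSE_WIDTH_STEP_MS = 0.01  # 10-us steps
INTERPHASE_RANGE_US = (0.0, 150.0)
INTERPHASE_STEP_US = 10.0
AMPLITUDE_STEP_DEVICE = 20  # device units


def _on_grid(value: float, step: float, tol: float = 1e-6) -> bool:
    return abs(value / step - round(value / step)) < tol


@dataclass
class StimProtocol:
    amplitudes_ma: tuple = (0.25, 0.50, 0.75, 1.00, 1.25)
    frequencies_hz: tuple = (60.0, 80.0, 100.0, 120.0, 140.0)
    repeats: int = 4
    pulses_per_burst: int = 10
    pulse_width_ms: float = 1.28
    interphase_us: float = 150.0
    interburst_s: float = 16.67
    polarity: str = "anodic_first"
    shape: str = "rectangular"
    custom_steps: tuple | None = None  # up to 16 per-step amplitudes
    amplitude_unit: str = "mA"  # or "device" (validated on the 20-unit grid)

    def __post_init__(self) -> None:
        lo, hi = PULSE_WIDTH_RANGE_MS
        if not (lo <= self.pulse_width_ms <= hi):
            raise ProtocolGridError(
                f"pulse width {self.pulse_width_ms} ms outside [{lo}, {hi}] ms"
            )
        if not _on_grid(self.pulse_width_ms, PULSE_WIDTH_STEP_MS):
            raise ProtocolGridError(
                f"pulse width {self.pulse_width_ms} ms not on the 10-us grid"
            )
        lo, hi = INTERPHASE_RANGE_US
        if not (lo <= self.interphase_us <= hi):
            raise ProtocolGridError(
                f"interphase width {self.interphase_us} us outside [{lo}, {hi}] us"
            )
        if not _on_grid(self.interphase_us, INTERPHASE_STEP_US):
            raise ProtocolGridError(
                f"interphase width {self.interphase_us} us not on the 10-us grid"
            )
        if self.polarity not in {"anodic_first", "cathodic_first"}:
            raise ProtocolGridError(f"unknown polarity {self.polarity!r}")
        if self.amplitude_unit == "device":
            for a in self.amplitudes_ma:
                if not _on_grid(a, AMPLITUDE_STEP_DEVICE):
                    raise ProtocolGridError(
                        f"amplitude {a} not on the {AMPLITUDE_STEP_DEVICE}-unit grid"
                    )
        if self.custom_steps is not None and len(self.custom_steps) > 16:
            raise ProtocolGridError("custom shape supports at most 16 steps")

    @property
    def n_bursts(self) -> int:
        return len(self.amplitudes_ma) * len(self.frequencies_hz) * self.repeats


@dataclass
class Burst:
    start_s: float
    amplitude: float
    frequency: float
    pulse_times: np.ndarray  # pulse onset times (s)


@dataclass
class PulseDetection:
    channel_id: str
    pulse_times_s: np.ndarray
    aligned_waveforms: np.ndarray  # (n_pulses, window)
    power: np.ndarray  # per-pulse sum of squares
    normalized_power: np.ndarray | None = None  # filled by propagation_stats


def schedule_bursts(
    p: StimProtocol, start_s: float = 1.0, seed: int | None = None
) -> list[Burst]:
    """Burst schedule for a protocol grid.

    Bursts are separated by ``interburst_s``; within a burst, pulse onsets
    are spaced 1/frequency apart (burst frequency = pulse-onset rate).
    Grid order is deterministic (amplitude-major); a seed shuffles the
    delivery order reproducibly.
    """
    combos = [
        (a, f)
        for a in p.amplitudes_ma
        for f in p.frequencies_hz
        for _ in range(p.repeats)
    ]
    if seed is not None:
        rng = np.random.default_rng(seed)
        rng.shuffle(combos)
    bursts = []
    t = start_s
    for a, f in combos:
        onsets = t + np.arange(p.pulses_per_burst) / f
        bursts.append(Burst(start_s=t, amplitude=a, frequency=f, pulse_times=onsets))
        t += p.interburst_s
    return bursts


def render_pulse(
    amplitude: float,
    pulse_width_ms: float,
    interphase_us: float,
    fs: float,
    polarity: str = "anodic_first",
    shape: str = "rectangular",
    custom_steps: tuple | None = None,
) -> np.ndarray:
    """Charge-balanced biphasic pulse waveform at sampling rate ``fs``.

    Phase 1 carries the polarity sign, then an interphase gap, then phase 2
    with the opposite sign and the mirrored shape, so phase areas cancel
    exactly.  ``custom_steps`` shapes each phase as up to 16 amplitude
    steps (all-equal steps degenerate to a rectangle).
    """
    n_phase = max(int(round(pulse_width_ms * 1e-3 * fs)), 1)
    n_gap = int(round(interphase_us * 1e-6 * fs))
    if shape == "rectangular":
        phase = np.full(n_phase, float(amplitude))
    elif shape == "custom_16_step":
        steps = np.asarray(custom_steps, dtype=float)
        idx = np.minimum(
            (np.arange(n_phase) * steps.size) // n_phase, steps.size - 1
        )
        phase = amplitude * steps[idx]
    else:
        raise ProtocolGridError(f"unknown pulse shape {shape!r}")
    sign = 1.0 if polarity == "anodic_first" else -1.0
    return np.concatenate([sign * phase, np.zeros(n_gap), -sign * phase])


def detect_pulses(
    rec: Recording,
    template: np.ndarray,
    threshold: float = 0.8,
    margin_ms: float = 2.0,
    min_separation_s: float | None = None,
) -> list[PulseDetection]:
    """Detect propagated pulses per channel by normalized cross-correlation.

    Correlation peaks at or above ``threshold`` are detections; aligned
    snippets (template window plus ``margin_ms``) are extracted at the peak
    lag.  ``min_separation_s`` defaults to the template duration.
    """
    template = np.asarray(template, dtype=float)
    t_norm = np.sqrt(np.sum(template**2))
    if t_norm == 0:
        raise CoreError("zero template")
    L = template.size
    if min_separation_s is None:
        min_separation_s = L / rec.fs
    min_sep = max(int(round(min_separation_s * rec.fs)), 1)
    margin = int(round(margin_ms * 1e-3 * rec.fs))

    detections = []
    for ch in range(rec.n_channels):
        x = rec.data[ch]
        num = fftconvolve(x, template[::-1], mode="valid")
        energy = fftconvolve(x**2, np.ones(L), mode="valid")
        # FFT roundoff leaves ~eps-scale garbage in silent stretches; floor
        # the window energy relative to the global maximum before dividing
        floor = max(energy.max(), 0.0) * 1e-9 + 1e-30
        ncc = num / (np.sqrt(np.maximum(energy, floor)) * t_norm)
        peaks = _pick_peaks(ncc, threshold, min_sep)
        times = peaks / rec.fs
        waves = np.empty((peaks.size, L + 2 * margin))
        keep = []
        for i, pk in enumerate(peaks):
            i0, i1 = pk - margin, pk + L + margin
            if i0 < 0 or i1 > x.size:
                continue
            waves[len(keep)] = x[i0:i1]
            keep.append(i)
        waves = waves[: len(keep)]
        times = times[keep]
        power = np.sum(waves**2, axis=1) if waves.size else np.empty(0)
        detections.append(
            PulseDetection(
                channel_id=rec.channel_ids[ch],
                pulse_times_s=times,
                aligned_waveforms=waves,
                power=power,
            )
        )
    return detections


def _pick_peaks(ncc: np.ndarray, threshold: float, min_sep: int) -> np.ndarray:
    above = np.where(ncc >= threshold)[0]
    if above.size == 0:
        return above
    peaks = []
    i = 0
    while i < above.size:
        j = i
        while j + 1 < above.size and above[j + 1] - above[j] <= min_sep:
            j += 1
        run = above[i: j + 1]
        peaks.append(run[np.argmax(ncc[run])])
        i = j + 1
    return np.array(peaks, dtype=int)


def propagation_stats(
    detections: list[PulseDetection],
    protocol: StimProtocol,
    bursts: list[Burst] | None = None,
    match_tol_s: float = 2e-3,
) -> pd.DataFrame:
    """Per-(amplitude, frequency) mean and SD of normalized pulse power per
    channel.

    Pulse power is the sum of squared aligned-snippet samples; the
    normalization constant is the single largest pulse power across all
    channels and pulses, so the largest pulse has normalized power exactly
    1.  Detections are assigned to protocol conditions by nearest scheduled
    pulse time.
    """
    if bursts is None:
        bursts = schedule_bursts(protocol)
    sched_times = np.concatenate([b.pulse_times for b in bursts])
    sched_cond = [(b.amplitude, b.frequency) for b in bursts for _ in b.pulse_times]
    order = np.argsort(sched_times)
    sched_times = sched_times[order]
    sched_cond = [sched_cond[i] for i in order]

    max_power = max((d.power.max() for d in detections if d.power.size), default=0.0)
    if max_power <= 0:
        raise CoreError("no detected pulses to normalize against")

    rows = []
    for det in detections:
        det.normalized_power = det.power / max_power
        for t, npow in zip(det.pulse_times_s, det.normalized_power):
            k = np.searchsorted(sched_times, t)
            k = min(max(k, 1), sched_times.size - 1)
            j = k - 1 if abs(t - sched_times[k - 1]) <= abs(t - sched_times[k]) else k
            if abs(t - sched_times[j]) > match_tol_s:
                continue
            amp, freq = sched_cond[j]
            rows.append(
                {"channel_id": det.channel_id, "amplitude": amp,
                 "frequency": freq, "norm_power": npow}
            )
    df = pd.DataFrame(rows)
    if df.empty:
        raise CoreError("no detections matched the schedule")
    out = (
        df.groupby(["channel_id", "amplitude", "frequency"])["norm_power"]
        .agg(mean_norm_power="mean", sd_norm_power="std", n_pulses="count")
        .reset_index()
    )
    out["sd_norm_power"] = out["sd_norm_power"].fillna(0.0)
    return out
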