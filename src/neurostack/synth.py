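"""Synthetic session generators with controllable ground truth.

Every input the pipeline consumes can be generated here: micro-wire
recordings with embedded spike trains (38.6-kHz class), motion artifacts,
walking sessions with boundary-modulated theta, verbal-memory sessions with
labelled word onsets, stimulation sessions with propagated pulse artifacts,
and single-channel theta-burst LFP for the closed-loop simulator.  All
generators are seed-deterministic and return a :class:`GroundTruth` rich
enough to score the downstream stage (spike recall, artifact recall,
decoder F1, propagation-gain recovery, phase-locking quality).

Modelling choices (see docs/methods.md): the background is 1/f^a colored
noise synthesized by spectral shaping of white noise (a = 1 by default,
the typical LFP spectrum); spike templates are biphasic 1.5-ms canonical
waveforms; theta is an amplitude-modulated sinusoid with intermittent
bursts (exponential burst durations, mean 1 s) rather than a continuous
oscillation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CoreError, Event, EventStream, Recording


@dataclass
class GroundTruth:
    """Hidden state of a synthetic session, used to score pipeline stages."""

    unit_spike_times: dict = field(default_factory=dict)  # unit id -> times (s)
    artifact_intervals: list = field(default_factory=list)  # (start_s, end_s, kind)
    theta_phase: np.ndarray | None = None  # instantaneous oscillator phase (rad)
    theta_envelope: np.ndarray | None = None  # oscillator amplitude envelope
    condition_labels: list = field(default_factory=list)  # per-event booleans
    propagation_gains: np.ndarray | None = None  # per-channel pulse gains
    slow_component: np.ndarray | None = None  # injected slow drift (per channel)
    unit_channels: dict = field(default_factory=dict)  # unit id -> channel index
    unit_templates: dict = field(default_factory=dict)  # unit id -> waveform


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def one_over_f_noise(
    n: int, fs: float, exponent: float, rng: np.random.Generator, sd: float = 1.0
) -> np.ndarray:
    """Colored noise with power spectrum ~ 1/f^exponent, scaled to SD ``sd``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shaping, n=n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def spike_template(kind: int, fs: float, width_ms: float = 1.5) -> np.ndarray:
    """Canonical biphasic extracellular waveform, absolute peak at 1.

    Three built-in shapes differing in trough width and rebound size.
    """
    n = max(int(round(width_ms * 1e-3 * fs)), 5)
    t = np.linspace(0, width_ms, n)  # ms
    params = {
        0: (0.40, 0.10, 0.45, 0.90, 0.28),  # narrow trough, moderate rebound
        1: (0.45, 0.16, 0.30, 1.00, 0.35),  # wide trough, small rebound
        2: (0.35, 0.08, 0.60, 0.80, 0.22),  # narrow trough, large rebound
    }
    t_tr, w_tr, reb, t_reb, w_reb = params[kind % 3]
    w = -np.exp(-(((t - t_tr) / w_tr) ** 2)) + reb * np.exp(
        -(((t - t_reb) / w_reb) ** 2)
    )
    return w / np.max(np.abs(w))


def poisson_spike_times(
    rate_hz: float,
    duration_s: float,
    rng: np.random.Generator,
    refractory_s: float = 0.003,
) -> np.ndarray:
    """Poisson spike times thinned by an absolute refractory period."""
    if rate_hz <= 0:
        raise CoreError(f"spike rate must be positive, got {rate_hz}")
    n_exp = int(rate_hz * duration_s * 2 + 50)
    isis = rng.exponential(1.0 / rate_hz, size=n_exp)
    times = np.cumsum(isis)
    times = times[times < duration_s]
    if times.size == 0:
        return times
    keep = np.concatenate([[True], np.diff(times) > refractory_s])
    return times[keep]


def _burst_envelope(
    n: int,
    fs: float,
    rng: np.random.Generator,
    mean_on_s: float = 1.0,
    mean_off_s: float = 1.0,
    edge_s: float = 0.05,
) -> np.ndarray:
    """Intermittent 0/1 burst gate with exponential on/off durations,
    smoothed by raised-cosine edges."""
    gate = np.zeros(n)
    t = 0.0
    on = bool(rng.integers(0, 2))
    while t * fs < n:
        dur = rng.exponential(mean_on_s if on else mean_off_s)
        i0, i1 = int(t * fs), min(int((t + dur) * fs), n)
        if on:
            gate[i0:i1] = 1.0
        t += dur
        on = not on
    ne = max(int(edge_s * fs), 1)
    kernel = np.hanning(2 * ne + 1)
    kernel /= kernel.sum()
    return np.convolve(gate, kernel, mode="same")


def _add_spikes(
    data: np.ndarray,
    fs: float,
    truth: GroundTruth,
    units: list[dict],
    duration_s: float,
    rng: np.random.Generator,
) -> None:
    """Insert spike templates at Poisson times; truth times mark the
    template's absolute peak sample."""
    for u_idx, unit in enumerate(units):
        tmpl = unit.get("template", u_idx)
        wave = (
            np.asarray(tmpl, dtype=float)
            if not np.isscalar(tmpl)
            else spike_template(int(tmpl), fs)
        )
        wave = wave / np.max(np.abs(wave)) * unit["amplitude"]
        peak_off = int(np.argmax(np.abs(wave)))
        ch = unit.get("channel", u_idx % data.shape[0])
        times = poisson_spike_times(unit["rate_hz"], duration_s, rng)
        uid = unit.get("id", f"u{u_idx}")
        kept = []
        for t_s in times:
            peak_idx = int(round(t_s * fs))
            i0 = peak_idx - peak_off
            i1 = i0 + wave.size
            if i0 < 0 or i1 > data.shape[1]:
                continue
            data[ch, i0:i1] += wave
            kept.append(peak_idx / fs)
        truth.unit_spike_times[uid] = np.array(kept)
        truth.unit_channels[uid] = ch
        truth.unit_templates[uid] = wave


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def default_units(n_channels: int) -> list[dict]:
    """Two units per channel at distinct amplitudes (60 and 100 uV)."""
    units = []
    for ch in range(n_channels):
        units.append(
            {"id": f"ch{ch}_a", "channel": ch, "template": 0, "amplitude": 60.0,
             "rate_hz": 3.0}
        )
        units.append(
            {"id": f"ch{ch}_b", "channel": ch, "template": 1, "amplitude": 100.0,
             "rate_hz": 6.0}
        )
    return units


def gen_microwire(
    n_channels: int = 16,
    fs: float = 38_600.0,
    duration_s: float = 60.0,
    noise_exponent: float = 1.0,
    noise_sd: float = 10.0,
    line_amp: float = 2.0,
    line_hz: float = 60.0,
    units: list[dict] | None = None,
    theta_amp: float = 15.0,
    theta_hz: float = 7.0,
    seed: int = 0,
) -> tuple[Recording, GroundTruth]:
    """Micro-wire recording: 1/f background + 60-Hz line + spike trains +
    intermittent theta.

    ``units`` is a list of ``{template, rate_hz, amplitude[, channel, id]}``
    dictionaries; templates are indices into the built-in shapes or explicit
    waveform arrays.  Amplitudes are in microvolts at the waveform's
    absolute peak.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    truth = GroundTruth()

    data = np.empty((n_channels, n), dtype=np.float64)
    for ch in range(n_channels):
        data[ch] = one_over_f_noise(n, fs, noise_exponent, rng, sd=noise_sd)
        if line_amp > 0:
            data[ch] += line_amp * np.sin(2 * np.pi * line_hz * t + rng.uniform(0, 2 * np.pi))

    if theta_amp > 0:
        phase = 2 * np.pi * theta_hz * t + rng.uniform(0, 2 * np.pi)
        env = _burst_envelope(n, fs, rng)
        theta = theta_amp * env * np.sin(phase)
        data += theta[None, :]
        truth.theta_phase = np.mod(phase, 2 * np.pi)
        truth.theta_envelope = env

    if units is None:
        units = default_units(n_channels)
    _add_spikes(data, fs, truth, units, duration_s, rng)

    rec = Recording(
        data=data, fs=fs, channel_ids=[f"mw{c}" for c in range(n_channels)]
    )
    return rec, truth


def sharp_transient_waveform(fs: float, duration_ms: float, rng) -> np.ndarray:
    """Sharp motion transient: fast-rising, exponentially decaying deflection
    with a damped oscillatory tail (broadband, spike-band overlapping)."""
    n = max(int(duration_ms * 1e-3 * fs), 4)
    t = np.arange(n) / fs
    tau = duration_ms * 1e-3 / 4.0
    f_ring = rng.uniform(400.0, 1500.0)
    w = np.exp(-t / tau) * np.cos(2 * np.pi * f_ring * t)
    return w / np.max(np.abs(w))


def inject_motion_artifacts(
    rec: Recording,
    n_sharp: int = 20,
    sharp_amp_sd_multiple: float = 10.0,
    sharp_duration_ms: float = 8.0,
    slow_amp: float = 0.0,
    slow_band_hz: float = 1.0,
    shared_across_channels: bool = True,
    seed: int = 0,
) -> tuple[Recording, GroundTruth]:
    """Add slow (<``slow_band_hz``) drifts and large sharp transients.

    Sharp transients exceed ``sharp_amp_sd_multiple`` times the per-channel
    SD and are shared across channels (with mild per-channel gain spread)
    when ``shared_across_channels`` — matching cable-motion artifacts that
    appear identically on a whole bundle.  Ground-truth intervals are
    recorded for both kinds.
    """
    rng = np.random.default_rng(seed)
    data = rec.data.copy()
    n_ch, n = data.shape
    truth = GroundTruth()

    if slow_amp > 0:
        # synthesized strictly below slow_band_hz: random spectrum masked in
        # the frequency domain, so injected power is entirely sub-band
        freqs = np.fft.rfftfreq(n, 1 / rec.fs)
        mask = (freqs > 0) & (freqs < slow_band_hz * 0.9)
        slow = np.zeros((n_ch if not shared_across_channels else 1, n))
        for i in range(slow.shape[0]):
            spec = np.zeros(freqs.size, dtype=complex)
            k = int(mask.sum())
            spec[mask] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
            s = np.fft.irfft(spec, n=n)
            slow[i] = s / max(s.std(), 1e-30) * slow_amp
        if shared_across_channels:
            gains = rng.uniform(0.9, 1.1, size=n_ch)
            slow_all = gains[:, None] * slow
        else:
            slow_all = slow
        data += slow_all
        truth.slow_component = slow_all
        truth.artifact_intervals.append((0.0, n / rec.fs, "slow"))

    if n_sharp > 0:
        dur_s = sharp_duration_ms * 1e-3
        margin = int(rec.fs * dur_s) + 1
        sd = data.std(axis=1)
        starts: list[int] = []
        attempts = 0
        while len(starts) < n_sharp and attempts < n_sharp * 200:
            attempts += 1
            cand = int(rng.integers(margin, n - margin))
            if all(abs(cand - s) > 3 * margin for s in starts):
                starts.append(cand)
        starts.sort()
        for s0 in starts:
            w = sharp_transient_waveform(rec.fs, sharp_duration_ms, rng)
            sign = rng.choice([-1.0, 1.0])
            if shared_across_channels:
                gains = rng.uniform(0.9, 1.1, size=n_ch)
            else:
                gains = (rng.uniform(0, 1, size=n_ch) < 0.5).astype(float)
                if not gains.any():
                    gains[rng.integers(0, n_ch)] = 1.0
            amp = sharp_amp_sd_multiple * sd  # per channel
            seg = slice(s0, s0 + w.size)
            data[:, seg] += (sign * gains * amp)[:, None] * w[None, :]
            truth.artifact_intervals.append(
                (s0 / rec.fs, (s0 + w.size) / rec.fs, "sharp")
            )

    return rec.copy_with(data), truth


def gen_walk_session(
    n_crossings: int = 10,
    crossing_duration_s: float = 10.0,
    theta_hz: float = 7.0,
    boundary_gain: float = 1.5,
    fs: float = 386.0,
    n_channels: int = 16,
    gap_s: float = 1.0,
    noise_exponent: float = 1.0,
    noise_sd: float = 10.0,
    theta_amp: float = 12.0,
    burst_on_s: float = 1.0,
    burst_off_s: float = 1.0,
    seed: int = 0,
) -> tuple[Recording, EventStream, GroundTruth]:
    """Back-and-forth walking session with boundary-modulated theta.

    The participant crosses the room ``n_crossings`` times; during the final
    third of each crossing (the boundary segment) each channel's theta
    amplitude is multiplied by ``boundary_gain``.  ``boundary_gain = 1`` is
    the null construction (no systematic boundary/inner difference).

    Theta bursts are generated independently per channel (independent burst
    envelopes and phases): micro-wires in a bundle pick up locally variable
    intermittent theta, and the permutation statistics downstream treat
    channels as exchangeable units, which a fully shared oscillator would
    violate.  ``truth.theta_phase`` and ``truth.theta_envelope`` are
    per-channel arrays of shape ``(n_channels, n_samples)``.
    """
    rng = np.random.default_rng(seed)
    pre_s = 1.0
    total_s = pre_s + n_crossings * (crossing_duration_s + gap_s) + 1.0
    n = int(round(total_s * fs))
    t = np.arange(n) / fs

    events = []
    gain = np.ones(n)
    for k in range(n_crossings):
        t0 = pre_s + k * (crossing_duration_s + gap_s)
        t1 = t0 + crossing_duration_s
        events.append(Event(t0, "crossing_start", {"crossing": k}))
        events.append(Event(t1, "crossing_end", {"crossing": k}))
        b0 = t0 + 2.0 * crossing_duration_s / 3.0
        gain[int(b0 * fs): int(t1 * fs)] = boundary_gain

    ch_scale = rng.uniform(0.7, 1.3, size=n_channels)
    data = np.empty((n_channels, n))
    phases = np.empty((n_channels, n))
    envelopes = np.empty((n_channels, n))
    for ch in range(n_channels):
        phase = 2 * np.pi * theta_hz * t + rng.uniform(0, 2 * np.pi)
        env = _burst_envelope(n, fs, rng, mean_on_s=burst_on_s,
                              mean_off_s=burst_off_s)
        phases[ch] = np.mod(phase, 2 * np.pi)
        envelopes[ch] = gain * env
        data[ch] = (
            one_over_f_noise(n, fs, noise_exponent, rng, sd=noise_sd)
            + theta_amp * ch_scale[ch] * gain * env * np.sin(phase)
        )

    truth = GroundTruth(theta_phase=phases, theta_envelope=envelopes)
    rec = Recording(data=data, fs=fs, channel_ids=[f"mw{c}" for c in range(n_channels)])
    return rec, EventStream(events), truth


def gen_memory_session(
    n_blocks: int = 9,
    words_per_block: int = 10,
    p_remember: float = 0.6,
    theta_effect: float = 1.0,
    fs: float = 250.0,
    n_channels: int = 16,
    n_regions: int = 2,
    word_duration_s: float = 2.0,
    isi_s: float = 0.8,
    block_gap_s: float = 12.0,
    theta_hz: float = 6.0,
    theta_amp: float = 8.0,
    noise_exponent: float = 1.0,
    noise_sd: float = 10.0,
    seed: int = 0,
) -> tuple[Recording, EventStream, GroundTruth]:
    """Verbal-memory session: labelled word onsets with onset-locked theta.

    Each word onset receives a theta burst over the 2-s presentation window;
    remembered-class onsets receive amplitude ``theta_amp * (1 +
    theta_effect)`` versus ``theta_amp`` for forgotten, so
    ``theta_effect = 0`` is the null construction (labels independent of
    the signal).  Channels are split into ``n_regions`` contiguous groups
    (brain-region branches for the decoder).
    """
    rng = np.random.default_rng(seed)
    onset_step = word_duration_s + isi_s
    pre_s = 6.0
    block_len = words_per_block * onset_step
    total_s = pre_s + n_blocks * (block_len + block_gap_s) + 6.0
    n = int(round(total_s * fs))
    t = np.arange(n) / fs

    phase = 2 * np.pi * theta_hz * t + rng.uniform(0, 2 * np.pi)
    burst_n = int(word_duration_s * fs)
    burst_shape = np.hanning(burst_n)

    events = []
    labels = []
    theta_env = np.zeros(n)
    for b in range(n_blocks):
        block_t0 = pre_s + b * (block_len + block_gap_s)
        for w in range(words_per_block):
            onset = block_t0 + w * onset_step
            remembered = bool(rng.random() < p_remember)
            labels.append(remembered)
            events.append(
                Event(onset, "word_onset", {"remembered": remembered, "block": b})
            )
            amp = 1.0 + (theta_effect if remembered else 0.0)
            i0 = int(round(onset * fs))
            seg = slice(i0, min(i0 + burst_n, n))
            theta_env[seg] += amp * burst_shape[: seg.stop - seg.start]

    theta = theta_amp * theta_env * np.sin(phase)
    region_size = int(np.ceil(n_channels / n_regions))
    region_ids = [min(c // region_size, n_regions - 1) for c in range(n_channels)]
    ch_scale = rng.uniform(0.8, 1.2, size=n_channels)
    data = np.empty((n_channels, n))
    for ch in range(n_channels):
        data[ch] = (
            one_over_f_noise(n, fs, noise_exponent, rng, sd=noise_sd)
            + ch_scale[ch] * theta
        )

    truth = GroundTruth(
        theta_phase=np.mod(phase, 2 * np.pi),
        theta_envelope=theta_env,
        condition_labels=labels,
    )
    rec = Recording(data=data, fs=fs, channel_ids=[f"mw{c}" for c in range(n_channels)])
    rec.region_ids = region_ids  # branch assignment per channel
    return rec, EventStream(events), truth


def gen_stim_session(
    amplitudes_ma: tuple = (0.25, 0.50, 0.75, 1.00, 1.25),
    frequencies_hz: tuple = (60.0, 80.0, 100.0, 120.0, 140.0),
    repeats: int = 4,
    pulses_per_burst: int = 10,
    pulse_width_ms: float = 1.28,
    interphase_us: float = 150.0,
    interburst_s: float = 16.67,
    fs: float = 6250.0,
    channel_gains: np.ndarray | None = None,
    gain_noise_sd: float = 0.0,
    noise_sd: float = 5.0,
    seed: int = 0,
):
    """Macro-channel stimulation session (propagation-mapping protocol).

    Default grid is the propagation protocol: 5 amplitudes x 5 frequencies
    x 4 repeats = 100 bursts of 10 biphasic rectangular pulses each.
    Pulses are rendered on every channel scaled by ``channel_gains`` (the
    propagation attenuation; 1 mA maps to 1,000 uV at gain 1) plus
    background noise.  Per-pulse multiplicative gain jitter of SD
    ``gain_noise_sd`` models delivery variability.

    Returns ``(Recording, StimProtocol, GroundTruth)``.
    """
    from .stim import StimProtocol, render_pulse, schedule_bursts

    rng = np.random.default_rng(seed)
    protocol = StimProtocol(
        amplitudes_ma=tuple(amplitudes_ma),
        frequencies_hz=tuple(frequencies_hz),
        repeats=repeats,
        pulses_per_burst=pulses_per_burst,
        pulse_width_ms=pulse_width_ms,
        interphase_us=interphase_us,
        interburst_s=interburst_s,
    )
    bursts = schedule_bursts(protocol)
    if channel_gains is None:
        channel_gains = np.exp(-np.arange(8) / 3.0)
    channel_gains = np.asarray(channel_gains, dtype=float)
    n_ch = channel_gains.size

    t_end = bursts[-1].pulse_times[-1] + pulse_width_ms * 1e-3 * 2 + 0.5
    n = int(round(t_end * fs))
    data = noise_sd * rng.standard_normal((n_ch, n))

    truth = GroundTruth(propagation_gains=channel_gains)
    pulse_records = []
    for burst in bursts:
        wave = render_pulse(
            amplitude=burst.amplitude * 1000.0,  # mA -> uV at unit gain
            pulse_width_ms=pulse_width_ms,
            interphase_us=interphase_us,
            fs=fs,
        )
        for pt in burst.pulse_times:
            i0 = int(round(pt * fs))
            if i0 + wave.size > n:
                continue
            jitter = (
                1.0 + gain_noise_sd * rng.standard_normal(n_ch)
                if gain_noise_sd > 0
                else np.ones(n_ch)
            )
            data[:, i0: i0 + wave.size] += (
                (channel_gains * jitter)[:, None] * wave[None, :]
            )
            pulse_records.append((pt, burst.amplitude, burst.frequency))
    truth.condition_labels = pulse_records

    rec = Recording(
        data=data, fs=fs, channel_ids=[f"macro{c}" for c in range(n_ch)]
    )
    return rec, protocol, truth


def gen_theta_lfp(
    duration_s: float = 300.0,
    fs: float = 500.0,
    theta_hz: float = 6.0,
    snr: float = 2.0,
    noise_exponent: float = 1.0,
    mean_on_s: float = 1.0,
    mean_off_s: float = 1.0,
    seed: int = 0,
) -> tuple[Recording, GroundTruth]:
    """Single-channel LFP with intermittent theta bursts for the closed-loop
    phase-locked stimulation simulator.

    ``snr`` is the theta burst amplitude divided by the broadband background
    SD.  The ground-truth oscillator phase is defined throughout (also
    between bursts).
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    phase = 2 * np.pi * theta_hz * t + rng.uniform(0, 2 * np.pi)
    env = _burst_envelope(n, fs, rng, mean_on_s=mean_on_s, mean_off_s=mean_off_s)
    background = one_over_f_noise(n, fs, noise_exponent, rng, sd=1.0)
    x = background + snr * env * np.sin(phase)
    truth = GroundTruth(theta_phase=np.mod(phase, 2 * np.pi), theta_envelope=env)
    rec = Recording(data=x[None, :], fs=fs, channel_ids=["lfp0"])
    return rec, truth
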