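"""Motion-artifact detection and removal for micro-wire recordings.

Slow transients (drifts below a few Hz) are removed by high-pass filtering.
Sharp transients — large broadband deflections shared across a bundle — are
isolated with ICA: the recording is decomposed into a small number of
components, the artifact component is band-filtered (300–3,000 Hz), its
analytic-signal envelope z-scored, and supra-threshold runs (default 4 SD)
are excised by linear interpolation with a 1-ms pad on each side.  The
fraction of samples removed is reported as the artifact-to-signal time
ratio (ASTR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .core import (
    CoreError,
    FilterSpec,
    Recording,
    filter_array,
)


class ICAConvergenceError(CoreError):
    pass


@dataclass
class ArtifactReport:
    removed_intervals: list = field(default_factory=list)  # (start, end) samples
    astr_percent: float = 0.0
    component_index: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.astr_percent <= 100.0:
            raise CoreError("astr_percent must be within [0, 100]")


def remove_slow_transients(rec: Recording, cutoff_hz: float = 1.0) -> Recording:
    """High-pass the recording to remove slow motion drifts.

    Default cutoff is 1 Hz (the analysis filter); a 4-Hz option matches the
    broader description of slow-transient content.
    """
    spec = FilterSpec(kind="highpass", cutoffs=(cutoff_hz,), order=8)
    return rec.copy_with(filter_array(rec.data, spec, rec.fs, zero_phase=True))


def _select_component(sources: np.ndarray, fs: float, band_hz: tuple) -> int:
    """Pick the ICA component whose band-filtered trace is most kurtotic.

    Sharp transients are heavy-tailed in the spike band, so kurtosis is a
    deterministic surrogate for the manual 'no single units' selection.
    """
    from scipy.stats import kurtosis as _kurt

    spec = FilterSpec(kind="bandpass", cutoffs=band_hz, order=4)
    filtered = filter_array(sources, spec, fs, zero_phase=True)
    return int(np.argmax(_kurt(filtered, axis=-1, fisher=True)))


def detect_sharp_transients(
    rec: Recording,
    n_components: int = 3,
    band_hz: tuple = (300.0, 3000.0),
    threshold_sd: float = 4.0,
    pad_ms: float = 1.0,
    smooth_ms: float = 5.0,
    min_duration_ms: float = 4.0,
    component_index: int | None = None,
    seed: int = 0,
) -> tuple[list[tuple[int, int]], int]:
    """Detect shared sharp transients via ICA.

    Returns ``(intervals, component_index)`` where intervals are half-open
    ``(start_sample, end_sample)`` runs of supra-threshold z-scored envelope
    samples of the selected component, padded by ``pad_ms`` on each side and
    merged when overlapping.  ``component_index`` overrides the automatic
    (max-kurtosis) component selection.

    The envelope is smoothed over ``smooth_ms`` before z-scoring: the raw
    analytic-signal magnitude of band-limited noise is Rayleigh-tailed, so
    an unsmoothed 4-SD threshold fires on noise alone; averaging over a few
    milliseconds Gaussianizes the envelope while leaving multi-millisecond
    motion transients intact.  Runs shorter than ``min_duration_ms`` are
    discarded before padding: motion transients last several milliseconds,
    whereas sub-millisecond threshold crossings are envelope noise.
    """
    from sklearn.decomposition import FastICA

    if n_components > rec.n_channels:
        raise CoreError("n_components cannot exceed the channel count")
    high = min(band_hz[1], rec.fs / 2 * 0.95)
    band = (band_hz[0], high)

    ica = FastICA(
        n_components=n_components,
        random_state=seed,
        max_iter=500,
        tol=1e-6,
        whiten="unit-variance",
    )
    import warnings

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        sources = ica.fit_transform(rec.data.T).T
    if any("did not converge" in str(w.message) for w in caught):
        raise ICAConvergenceError(
            f"FastICA did not converge in 500 iterations "
            f"(n_components={n_components}, n_samples={rec.n_samples})"
        )

    if component_index is None:
        component_index = _select_component(sources, rec.fs, band)
    comp = sources[component_index]

    spec = FilterSpec(kind="bandpass", cutoffs=band, order=4)
    comp_f = filter_array(comp, spec, rec.fs, zero_phase=True)
    env = np.abs(hilbert(comp_f))
    if smooth_ms > 0:
        w = max(int(round(smooth_ms * 1e-3 * rec.fs)), 1)
        env = np.convolve(env, np.ones(w) / w, mode="same")
    z = (env - env.mean()) / env.std()

    above = z > threshold_sd
    pad = int(round(pad_ms * 1e-3 * rec.fs))
    min_len = int(round(min_duration_ms * 1e-3 * rec.fs))
    intervals = _runs_to_intervals(above, pad, rec.n_samples, min_len=min_len)
    return intervals, component_index


def _runs_to_intervals(
    mask: np.ndarray, pad: int, n: int, min_len: int = 0
) -> list[tuple[int, int]]:
    """Maximal True runs of at least ``min_len`` samples, padded by ``pad``
    samples each side and merged."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(n)
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if e - s < min_len:
            continue
        s, e = max(0, s - pad), min(n, e + pad)
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


def interpolate_intervals(
    rec: Recording, intervals: list[tuple[int, int]], component_index: int | None = None
) -> tuple[Recording, ArtifactReport]:
    """Replace samples in each interval by the line between its boundary
    samples; everything outside is untouched (bit-exact).

    ASTR is the removed-sample fraction times 100.
    """
    data = rec.data.copy()
    n = rec.n_samples
    removed = np.zeros(n, dtype=bool)
    for s, e in intervals:
        if not (0 <= s <= e <= n):
            raise CoreError(f"interval ({s}, {e}) outside recording of {n} samples")
        if e <= s:
            continue
        removed[s:e] = True
        left = s - 1
        right = e  # first sample after the interval
        for ch in range(rec.n_channels):
            lv = data[ch, left] if left >= 0 else data[ch, right] if right < n else 0.0
            rv = data[ch, right] if right < n else lv
            # line between boundary samples, evaluated at interior positions
            k = e - s
            frac = (np.arange(1, k + 1)) / (k + 1)
            data[ch, s:e] = lv + (rv - lv) * frac
    astr = 100.0 * removed.sum() / n
    report = ArtifactReport(
        removed_intervals=list(intervals),
        astr_percent=astr,
        component_index=component_index,
    )
    return rec.copy_with(data), report


def remove_artifacts(
    rec: Recording,
    slow_cutoff_hz: float = 1.0,
    n_components: int = 3,
    band_hz: tuple = (300.0, 3000.0),
    threshold_sd: float = 4.0,
    pad_ms: float = 1.0,
    seed: int = 0,
) -> tuple[Recording, ArtifactReport]:
    """Full pipeline: slow-drift high-pass, ICA sharp-transient detection,
    linear interpolation.  Convenience wrapper used by the analysis drivers."""
    cleaned = remove_slow_transients(rec, slow_cutoff_hz)
    intervals, comp = detect_sharp_transients(
        cleaned,
        n_components=n_components,
        band_hz=band_hz,
        threshold_sd=threshold_sd,
        pad_ms=pad_ms,
        seed=seed,
    )
    return interpolate_intervals(cleaned, intervals, component_index=comp)
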