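"""Device-concordance metrics between two simultaneously recorded traces.

The metric set mirrors standard dual-device iEEG comparisons: Pearson
correlation, Hjorth parameters (activity, mobility, complexity), Pearson
(non-excess) kurtosis, artifact spike count (z-scored samples beyond +-6 at
250 Hz) and 55–65-Hz line-noise band power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import ConstantChannelError, CoreError, Recording, resample


@dataclass
class ConcordanceReport:
    pearson_r: float
    hjorth_a: dict
    hjorth_b: dict
    kurtosis_a: float
    kurtosis_b: float
    artifact_spike_count_a: int
    artifact_spike_count_b: int
    power_60hz_a: float
    power_60hz_b: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.pearson_r <= 1.0 + 1e-12:
            raise CoreError("pearson_r outside [-1, 1]")


def hjorth_params(y: np.ndarray, fs: float) -> dict:
    """Hjorth activity, mobility and complexity.

    Activity = var(y); Mobility = sqrt(var(dy/dt)/var(y));
    Complexity = Mobility(dy/dt)/Mobility(y).  The derivative is the
    forward first difference scaled by fs.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise CoreError("need at least 3 samples")
    if np.var(y) == 0:
        raise ConstantChannelError("constant signal has zero activity")
    dy = np.diff(y) * fs
    ddy = np.diff(dy) * fs
    activity = float(np.var(y))
    mobility = float(np.sqrt(np.var(dy) / np.var(y)))
    mobility_d = float(np.sqrt(np.var(ddy) / np.var(dy)))
    return {
        "activity": activity,
        "mobility": mobility,
        "complexity": mobility_d / mobility,
    }


def kurtosis(y: np.ndarray) -> float:
    """Pearson (non-excess) kurtosis E(y-mu)^4 / sigma^4, no small-sample
    correction (Gaussian -> 3)."""
    y = np.asarray(y, dtype=float)
    mu = y.mean()
    s2 = np.mean((y - mu) ** 2)
    if s2 == 0:
        raise ConstantChannelError("constant signal has undefined kurtosis")
    return float(np.mean((y - mu) ** 4) / s2**2)


def artifact_spike_count(
    y: np.ndarray, fs: float, z_bound: float = 6.0, fs_target: float = 250.0
) -> int:
    """Count of z-scored samples with |z| > z_bound after resampling to
    ``fs_target`` (250 Hz)."""
    y = _to_target(y, fs, fs_target)
    sd = y.std()
    if sd == 0:
        return 0
    z = (y - y.mean()) / sd
    return int(np.sum(np.abs(z) > z_bound))


def power_60hz(
    y: np.ndarray, fs: float, band: tuple = (55.0, 65.0), fs_target: float = 250.0
) -> float:
    """Band power over ``band`` (55–65 Hz) by periodogram integration at
    ``fs_target`` sampling (unit-amplitude 60-Hz sine -> ~0.5)."""
    y = _to_target(y, fs, fs_target)
    freqs, psd = sps.periodogram(y, fs=fs_target)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.trapezoid(psd[sel], freqs[sel]))


def _to_target(y: np.ndarray, fs: float, fs_target: float) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if abs(fs - fs_target) < 1e-9:
        return y
    rec = Recording(data=y[None, :], fs=fs, channel_ids=["x"])
    return resample(rec, fs_target).data[0]


def concordance_report(
    a: np.ndarray, b: np.ndarray, fs: float, fs_target: float = 250.0
) -> ConcordanceReport:
    """All concordance metrics for two aligned traces of equal length."""
    a = _to_target(a, fs, fs_target)
    b = _to_target(b, fs, fs_target)
    if a.size != b.size:
        raise CoreError("traces must have equal length after resampling")
    r = float(np.corrcoef(a, b)[0, 1])
    return ConcordanceReport(
        pearson_r=r,
        hjorth_a=hjorth_params(a, fs_target),
        hjorth_b=hjorth_params(b, fs_target),
        kurtosis_a=kurtosis(a),
        kurtosis_b=kurtosis(b),
        artifact_spike_count_a=artifact_spike_count(a, fs_target),
        artifact_spike_count_b=artifact_spike_count(b, fs_target),
        power_60hz_a=power_60hz(a, fs_target),
        power_60hz_b=power_60hz(b, fs_target),
    )
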