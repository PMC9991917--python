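"""Time-frequency and power-spectrum computations.

Scalograms use the generalized Morse wavelet (symmetry parameter gamma = 3,
time-bandwidth product 60 by default) evaluated at 70 logarithmically spaced
frequencies from 1 to 125 Hz — the analytic wavelet family behind modern
CWT implementations.  The contract here is peak location and quadratic
amplitude scaling, not coefficient-level equality with any particular
toolbox.

Band-limited power uses the oscillation-detection convention: a fixed
six-cycle Morlet wavelet evaluated on a 3–90-Hz grid with 0.25-Hz steps
below 30 Hz and 1-Hz steps from 30 Hz up; per-sample band power is the sum
of wavelet power over the grid frequencies inside the band, z-scored per
channel over the entire series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import CoreError


@dataclass
class Scalogram:
    power: np.ndarray  # (n_times, n_freqs)
    freqs_hz: np.ndarray
    fs: float
    normalization: str = "morse-peak2"
    coi_mask: np.ndarray | None = None  # True where inside the cone of influence

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise CoreError("frequency axis must be strictly increasing")
        if np.any(self.power < 0):
            raise CoreError("power must be non-negative")


@dataclass
class BandpowerSeries:
    values: np.ndarray  # z-scored band power over time
    band_hz: tuple
    channel_id: str = "ch0"
    fs: float = 1.0
    t0: float = 0.0
    raw: np.ndarray | None = None  # pre-z-score band power (additive across bands)

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs


# ---------------------------------------------------------------------------
# Morse-wavelet scalogram
# ---------------------------------------------------------------------------

def _morse_freq_response(omega: np.ndarray, gamma: float, beta: float) -> np.ndarray:
    """Morse wavelet in the frequency domain, peak value 2 (analytic)."""
    psi = np.zeros_like(omega)
    pos = omega > 0
    # log-domain evaluation, normalized at the peak frequency (beta/gamma)^(1/gamma)
    log_peak = (beta / gamma) * (np.log(beta) - np.log(gamma)) - beta / gamma
    psi[pos] = 2.0 * np.exp(beta * np.log(omega[pos]) - omega[pos] ** gamma - log_peak)
    return psi


def cwt_scalogram(
    x: np.ndarray,
    fs: float,
    n_freqs: int = 70,
    f_range_hz: tuple = (1.0, 125.0),
    gamma: float = 3.0,
    time_bandwidth: float = 60.0,
) -> Scalogram:
    """Continuous wavelet transform power scalogram.

    Input is expected to be z-scored.  Cone-of-influence samples (within one
    wavelet time-SD of either edge) are flagged in ``coi_mask``, not trimmed.
    """
    x = np.asarray(x, dtype=float)
    if f_range_hz[0] <= 0 or f_range_hz[1] > fs / 2:
        raise CoreError("f_range must be inside (0, fs/2]")
    beta = time_bandwidth / gamma
    freqs = np.logspace(np.log10(f_range_hz[0]), np.log10(f_range_hz[1]), n_freqs)
    peak_omega = (beta / gamma) ** (1.0 / gamma)

    n = x.size
    xhat = np.fft.fft(x)
    omega = 2 * np.pi * np.fft.fftfreq(n, 1 / fs)
    power = np.empty((n, n_freqs))
    coi = np.zeros((n, n_freqs), dtype=bool)
    # wavelet duration ~ sqrt(beta*gamma)/omega_c cycles -> time SD in seconds
    sd_cycles = np.sqrt(time_bandwidth) / (2 * np.pi)
    idx = np.arange(n)
    for j, f in enumerate(freqs):
        scale = peak_omega / (2 * np.pi * f)
        w = np.fft.ifft(xhat * _morse_freq_response(scale * omega, gamma, beta))
        power[:, j] = np.abs(w) ** 2
        edge = int(np.ceil(sd_cycles / f * fs))
        coi[:, j] = (idx < edge) | (idx >= n - edge)
    return Scalogram(power=power, freqs_hz=freqs, fs=fs, coi_mask=coi)


# ---------------------------------------------------------------------------
# FFT / Welch spectra
# ---------------------------------------------------------------------------

def fft_power(
    x: np.ndarray, fs: float, normalize_by: str = "transform"
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided FFT power spectrum.

    The transform length is the largest power of 2 strictly less than
    ``len(x)``; coefficients are normalized by that length
    (``normalize_by='original'`` normalizes by the full trace length
    instead), and one-sided power is ``2 |c|^2`` (DC and Nyquist bins are
    not doubled).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise CoreError("need at least 2 samples")
    nfft = 2 ** int(np.floor(np.log2(x.size - 1))) if x.size > 2 else 2
    norm = nfft if normalize_by == "transform" else x.size
    c = np.fft.rfft(x[:nfft]) / norm
    power = np.abs(c) ** 2
    power[1:] *= 2.0
    if nfft % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(nfft, 1 / fs)
    return freqs, power


def welch_psd(
    x: np.ndarray,
    fs: float,
    n_segments: int = 8,
    overlap: float = 0.5,
    window: str = "hamming",
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density (density scaling, V^2/Hz).

    Default segmentation: 8 segments with 50% overlap, Hamming window.
    """
    x = np.asarray(x, dtype=float)
    nperseg = max(int(x.size / (n_segments * (1 - overlap) + overlap)), 8)
    return sps.welch(x, fs=fs, window=window, nperseg=nperseg,
                     noverlap=int(nperseg * overlap))


# ---------------------------------------------------------------------------
# Fixed-cycle Morlet band power
# ---------------------------------------------------------------------------

def bosc_grid(
    f_min: float = 3.0,
    f_max: float = 90.0,
    fine_step: float = 0.25,
    coarse_step: float = 1.0,
    split_hz: float = 30.0,
) -> np.ndarray:
    """Analysis frequency grid: fine steps below ``split_hz``, coarse steps
    from ``split_hz`` to ``f_max`` inclusive (169 points by default)."""
    fine = np.arange(f_min, split_hz, fine_step)
    coarse = np.arange(split_hz, f_max + coarse_step / 2, coarse_step)
    return np.concatenate([fine, coarse])


def _morlet_power(x: np.ndarray, fs: float, freqs: np.ndarray, n_cycles: int):
    """Power time series at each frequency via frequency-domain Morlet
    (sigma_f = f/n_cycles, analytic).  Batched over frequencies with a
    fast-length FFT."""
    from scipy import fft as sfft

    n = x.size
    nfft = sfft.next_fast_len(n)
    xhat = sfft.fft(x, n=nfft)
    f_axis = sfft.fftfreq(nfft, 1 / fs)
    sigma_f = freqs / n_cycles
    kernels = np.exp(
        -0.5 * ((f_axis[None, :] - freqs[:, None]) / sigma_f[:, None]) ** 2
    )
    kernels[:, f_axis < 0] = 0.0
    w = sfft.ifft(xhat[None, :] * 2.0 * kernels, axis=1)[:, :n]
    return np.abs(w) ** 2


def bosc_bandpower(
    x: np.ndarray,
    fs: float,
    band_hz: tuple,
    n_cycles: int = 6,
    grid: np.ndarray | None = None,
    channel_id: str = "ch0",
    t0: float = 0.0,
) -> BandpowerSeries:
    """Band power over time: sum of six-cycle Morlet wavelet power over the
    grid frequencies inside ``band_hz`` (low-inclusive, high-exclusive so
    adjacent bands tile additively), z-scored over the entire series.
    """
    x = np.asarray(x, dtype=float)
    if grid is None:
        grid = bosc_grid()
    low, high = band_hz
    sel = grid[(grid >= low) & (grid < high)]
    if sel.size == 0:
        raise CoreError(f"no grid frequencies inside band {band_hz}")
    if sel.max() >= fs / 2:
        raise CoreError("band extends past Nyquist")
    raw = _morlet_power(x, fs, sel, n_cycles).sum(axis=0)
    sd = raw.std()
    if sd == 0:
        raise CoreError("constant band power; cannot z-score")
    z = (raw - raw.mean()) / sd
    return BandpowerSeries(
        values=z, band_hz=tuple(band_hz), channel_id=channel_id, fs=fs, t0=t0,
        raw=raw,
    )
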