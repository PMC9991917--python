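# neurostack

Analysis pipeline for wearable intracranial recording and closed-loop
stimulation studies: micro-wire single units and LFP, macro-channel iEEG,
programmable stimulation bursts, and real-time-style neural decoding —
implemented as a tested Python library over synthetic sessions with known
ground truth.

## Who this is for

Electrophysiologists and methods engineers who need the full analysis
chain of an ambulatory human single-unit/LFP platform as reusable,
verifiable code: every stage consumes either recordings from disk
(raw float32 + JSON sidecar, EDF) or seeded synthetic sessions whose
hidden state (spike times, artifact intervals, oscillator phase,
condition labels, propagation gains) scores the stage's output.

## What it computes

- **Artifact removal** — slow (<1–4 Hz) drifts by high-pass filtering;
  sharp shared transients by ICA: the 300–3,000-Hz-filtered component's
  z-scored envelope is thresholded at 4 SD and supra-threshold blocks
  (±1 ms pad) are excised by linear interpolation. Reported as ASTR, the
  removed-sample fraction.
- **Spike pipeline** — threshold detection at k·σ with
  σ = median(|x|)/0.6745, PCA/k-means clustering, the acceptance rule
  (> 250 spikes, ≤ 1% of inter-spike intervals < 3 ms), firing rates
  (50-ms bins, 50-point Gaussian), SNR = max|mean waveform|/3σ_noise,
  yield (accepted units per channel) and ARI (mean % spike-count change
  after artifact removal).
- **Spectral analysis** — Morse-wavelet scalograms (gamma 3,
  time–bandwidth 60, 70 log frequencies 1–125 Hz), FFT and Welch power
  spectra, and six-cycle-Morlet band power on the 3–90-Hz oscillation
  grid (0.25-Hz steps below 30 Hz, 1-Hz above), z-scored per channel.
- **Boundary analysis** — crossings split at 1/3 and 2/3 of their
  duration into inner/boundary conditions; sample counts equalized by
  500 random subsamples; two-sided paired sign-flip permutation test
  (10,000 permutations, exhaustive when 2^n ≤ 10,000) on per-channel
  theta (3–12 Hz) band power.
- **Concordance** — Pearson r, Hjorth activity/mobility/complexity,
  Pearson kurtosis, artifact spike count (|z| > 6 at 250 Hz) and
  55–65-Hz band power between two simultaneously recorded traces.
- **Stimulation engine** — burst schedules on the device grid
  (pulse width 10–1,280 µs in 10-µs steps, interphase 0–150 µs),
  charge-balanced biphasic pulse rendering (rectangular or 16-step
  custom), pulse detection by normalized cross-correlation against the
  delivered template, and propagation statistics: per-condition mean/SD
  of pulse power normalized by the single largest propagated pulse.
- **Phase-locked stimulation (PLS)** — a causal loop (band-pass 3–8 Hz,
  trailing-RMS power detector, zero-crossing phase tracker, configurable
  round-trip latency and refractory period) scored by the circular
  variance of ground-truth phase at trigger times.
- **Memory decoder** — 10-s Gaussian-weighted chunks around labelled
  word onsets at 250 Hz feed per-region CNN1D(32) → CNN1D(64) → LSTM(64)
  branches with a dense head; binary cross-entropy, RMSprop (lr 0.001),
  F1 at the 0.5 threshold, ROC/AUC; online transfer learning retrains
  only the dense head with branch parameters frozen bit-exactly. The
  network and its backpropagation are implemented in numpy and verified
  against finite differences.

## Worked example

Closed-loop phase locking on synthetic theta-burst LFP:

```python
from neurostack.synth import gen_theta_lfp
from neurostack.pls import PLSConfig, run_pls

rec, truth = gen_theta_lfp(duration_s=300.0, fs=500.0, theta_hz=6.0,
                           snr=2.0, seed=1)
log = run_pls(rec, truth, PLSConfig(band_hz=(3.0, 8.0),
                                    power_threshold=1.5, latency_ms=1.57))
print(log.trigger_times_s.size, round(log.circ_variance, 4))
```

prints

```
157 0.0287
```

— the loop emitted 157 stimulation triggers over 300 s, and the
ground-truth oscillator phases at those triggers have circular variance
0.0287 (0 = perfect phase locking, 1 = uniform phases), comfortably below
the 0.3 the detection hardware class achieves in vitro. A constant loop
latency rotates the locked phase by 2πf·latency but does not degrade the
circular variance (see `analysis/07_pls_simulation.py`).

The numbered drivers under `analysis/` walk the full chain the same way —
session simulation, artifact removal scores, spike quality (yield/SNR/ARI),
boundary theta statistics, concordance, stimulation propagation, PLS, and
the decoder with transfer learning — each printing its findings and
writing tables under `results/`.

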