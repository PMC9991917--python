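# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `neurostack`, and states what the shipped tests do and
do not demonstrate.

## Scope

The package re-implements, as a tested pipeline over synthetic data, the
analysis chain of a wearable intracranial recording/stimulation platform
study: micro-wire recordings (38.6-kHz class) and macro-channel recordings
(6,250 Hz) are simulated with controllable ground truth; motion artifacts
are detected and removed; spikes are sorted and scored; theta band power is
compared between behavioural conditions; dual-device concordance metrics,
stimulation-pulse propagation statistics, a causal phase-locked
stimulation (PLS) loop, and a CNN1D+LSTM memory decoder with transfer
learning complete the chain. Hardware, firmware, networking, video
processing and electrode localization are out of scope.

## Signal primitives

- Filters are Butterworth (high/low/bandpass) and a 2nd-order IIR notch
  with Q = 30 at 60 Hz. Analysis stages filter zero-phase
  (forward–backward); the PLS simulator filters causally (single pass),
  because a closed loop cannot use future samples.
- Resampling is polyphase with anti-alias filtering; 38,600 → 386 Hz is an
  exact 1/100 rational ratio.
- Amplitudes are microvolts internally; times are float64 seconds; sample
  indexing is 0-based; intervals are half-open `[start, end)`.
- The raw on-disk container is little-endian float32, channel-interleaved,
  with a JSON sidecar (`fs`, `n_channels`, `channel_ids`, `unit`, `t0`);
  round-trips are bit-exact. EDF is read through MNE and is exact to the
  format's 16-bit quantization.

## Spectral analysis

- Scalograms use the generalized Morse wavelet (symmetry parameter
  gamma = 3, time–bandwidth product 60; hence beta = 20), evaluated in the
  frequency domain on 70 logarithmically spaced frequencies from 1 to
  125 Hz. The contract is peak location and quadratic amplitude scaling,
  not coefficient-level equality with any particular toolbox's CWT.
  Cone-of-influence samples (within one wavelet time-SD of an edge) are
  flagged, not trimmed.
- The FFT power spectrum uses a transform length equal to the largest
  power of 2 strictly below the trace length, normalizes coefficients by
  the transform length (a flag selects the original length instead), and
  doubles all one-sided bins except DC and Nyquist.
- Welch PSDs default to 8 segments, 50% overlap, Hamming window (density
  scaling).
- Band power over time uses a fixed six-cycle complex Morlet
  (sigma_f = f/6) on the oscillation-analysis grid: 0.25-Hz steps from 3
  to 29.75 Hz and 1-Hz steps from 30 to 90 Hz (169 points). A band's power
  series is the sum over grid frequencies inside the band
  (low-inclusive, high-exclusive, so adjacent bands tile additively), then
  z-scored per channel over the entire series.

## Motion-artifact removal

Slow drifts are removed with an 8th-order 1-Hz high-pass (a 4-Hz cutoff is
available, matching the broader description of slow-transient content).
Sharp transients are isolated with FastICA (3 components, deterministic
seed, tol 1e-6, max 500 iterations); the analysis selects the component
whose 300–3,000-Hz-filtered trace has maximal kurtosis — a deterministic
surrogate for manually choosing the component without single units — with
a manual override. The component's analytic-signal envelope is smoothed
over 5 ms, z-scored, and thresholded at 4 SD; supra-threshold runs shorter
than 4 ms are discarded, the rest are padded by 1 ms per side, merged, and
excised by linear interpolation between the interval's boundary samples.

Two numerical choices extend the plain "4 SD of the z-scored envelope"
rule and matter in practice: the raw Hilbert envelope of band-limited
noise is Rayleigh-tailed, so an unsmoothed 4-SD threshold fires hundreds
of times per minute on clean noise; 5-ms averaging Gaussianizes the
envelope, and the 4-ms minimum-duration rule removes the remaining
sub-millisecond noise crossings while keeping every multi-millisecond
motion transient. With both, the false-alarm rate on stationary noise is
below one interval per minute while recall on injected 10-SD transients
stays at 1.0.

ASTR (artifact-to-signal time ratio) is exactly the removed-sample
fraction × 100. ARI (artifact-removal impact) is the mean percent change
in per-unit spike counts across units matched before/after removal
(greedy matching by mean-waveform correlation > 0.9, ties broken by
spike-time overlap).

## Spike pipeline

Detection band-passes 300–3,000 Hz, estimates noise as
median(|x|)/0.6745, and takes local extrema above a 5-SD threshold with
1-ms dead time; snippets (1.5 ms) are aligned at the extremum. Clustering
projects snippets onto two principal components and runs k-means with k
chosen by silhouette (k ≤ 5; a split below silhouette 0.5 falls back to a
single cluster). Any sorter satisfies the downstream contract; the
acceptance rule is the fixed one: strictly more than 250 spikes and at
most 1% of ISIs below 3 ms. Firing rates count spikes in non-overlapping
50-ms bins convolved with a unit-area 50-point Gaussian (SD 50/6 points so
the window spans ±3 SD); tails are folded back so the total count is
conserved exactly. SNR is the absolute peak of the mean waveform over
three times the background-noise SD (estimated from the band-filtered
trace).

## Boundary analysis and statistics

Each crossing `[t0, t1]` is split at `t0 + (t1−t0)/3` and
`t0 + 2(t1−t0)/3`; the middle third is *inner*, the final third
*boundary*. Since the two conditions have equal durations by construction,
the 500-iteration subsample equalization reduces to direct means there; it
activates whenever counts differ. The paired permutation test sign-flips
per-channel condition differences; the two-sided p-value is the fraction
of permuted |means| at or above the observed |mean| (ties counted, no +1
smoothing by default; a smoothed (k+1)/(n+1) estimator and one-sided
alternatives are available). When 2^n ≤ n_perm the test enumerates all
sign patterns exactly instead of sampling.

## Synthetic data

The generators define the study conditions; their defaults follow the
study design where it is stated: 10 crossings for the walking task; 9
blocks × 10 words (2-s words, 0.8-s inter-stimulus interval) for the
memory task; 16 channels for both; the 100-burst stimulation grid
(0.25–1.25 mA × 60–140 Hz × 4 repeats, 10 pulses per burst, 1.28-ms
pulses, 150-µs interphase, 16.67-s interburst delay); 300 s of LFP for the
PLS benchmark; a 1.57-ms round-trip loop latency.

Modelling choices where the design is open:

- Background is 1/f^a colored noise (a = 1, SD 10 µV) made by spectral
  shaping of white noise, plus an optional 60-Hz line component.
- Spike templates are biphasic 1.5-ms canonical waveforms (three shapes);
  amplitude is defined at the absolute peak; spike times are Poisson with
  a 3-ms refractory thinning.
- Theta is an amplitude-modulated sinusoid with intermittent bursts
  (exponential on/off durations, mean 1 s each) rather than a continuous
  oscillation, matching the intermittent-oscillation view behind the
  band-power analysis. In walking sessions each channel gets an
  independent burst envelope and phase: micro-wires pick up locally
  variable theta, and the permutation test downstream treats channels as
  exchangeable units — a fully shared oscillator would make the
  per-channel condition differences one effective sample.
- The boundary effect multiplies theta amplitude by `boundary_gain` during
  the final third of each crossing; `boundary_gain = 1` is the null.
- The memory effect is an onset-locked theta burst over the 2-s word
  window whose amplitude is `(1 + theta_effect)` for remembered versus 1
  for forgotten words; `theta_effect = 0` is the null.
- Sharp motion artifacts are fast-rising, exponentially decaying
  transients with a 400–1,500-Hz ringing tail, ~8 ms long, scaled to a
  multiple (default 10×) of each channel's SD and shared across channels
  with ±10% gain spread; slow artifacts are synthesized strictly below
  the stated band edge in the frequency domain.
- Stimulation sessions render the scheduled biphasic pulses on every
  channel scaled by per-channel propagation gains (1 mA ≙ 1,000 µV at
  unit gain) plus Gaussian noise and optional per-pulse gain jitter.

What the generators do **not** emulate: spike waveform drift and overlap
statistics of real bundles, non-stationary noise floors, stimulation
artifact nonlinearity/saturation, behavioural confounds between
conditions, or volume-conduction correlation structure. Passing tests
therefore demonstrate correctness of the analysis chain and recoverability
of planted effects, not expected performance on patient recordings.

## PLS loop

The causal loop band-passes 3–8 Hz (4th-order, single pass), computes a
trailing 500-ms RMS power z-scored against a trailing 10-s baseline
(cumulative sums only — no future samples; the baseline SD is floored, so
a perfectly stationary input has z ≈ 0), and tracks phase with upward
zero crossings: the running period estimate comes from the last two
crossings (sub-sample interpolated), and a trigger is scheduled
`target_phase/2π` of a period after a crossing if power exceeds the
threshold (default 1.5 z) and the refractory period (default 50 ms) has
elapsed. Implausible period estimates (outside half-to-double the band)
are skipped. Triggers are delayed by the configured loop latency; a
constant latency rotates the locked phase by 2πf·latency without
affecting the circular variance, CV = 1 − |mean resultant|, computed on
the ground-truth oscillator phase at trigger times.

## Memory decoder

The decoder is implemented from scratch in numpy (layers with analytically
derived backpropagation, verified against finite differences): per-region
branches of Conv1D(32 filters) → Conv1D(64 filters) → average pooling →
LSTM(64, final state), concatenated into a dense head (32 units, ReLU)
and a 1-unit sigmoid classifier. Dropout is 0.2 after conv/dense layers
and 0.1 on LSTM inputs with 0.5 recurrent (variational) dropout; conv and
dense weights carry an L2 penalty (1e-4). Training minimizes binary
cross-entropy with RMSprop (learning rate 0.001, rho 0.9). Kernel length
7 with stride 4 on both convolutions and pool 4 before the LSTM reduce the
2,500-sample chunk to a ~38-step sequence; only filter counts and the
LSTM width are fixed by the study design, and the sequence-length
reduction is what makes CPU training of the numpy implementation
practical at no cost to the planted onset-locked theta signal.

Windowing: 0.1-Hz high-pass, anti-aliased resampling to 250 Hz, 10-s
chunks (−5 to +5 s around each labelled word onset) multiplied by a
Gaussian weight profile (SD 2.5 s, peak 1 at onset); edge-clipped onsets
are dropped with a warning. Chunks are divided by the session-wide SD —
one scale for the whole recording — which brings microvolts to unit order
without erasing between-event amplitude differences. Class balancing
subsamples the majority class; balancing matters for calibration: an
unbalanced training prior shifts the score distribution off 0.5 and turns
threshold-0.5 F1 into a biased statistic on null data.

Transfer learning freezes all branch parameters (bit-identical before and
after, asserted) and retrains only the two dense layers on an
accumulating, shuffled pool of chunks after each training block, starting
each retraining from the previous coefficients; remaining blocks are
scored as the prediction phase. Serialization is a JSON weight manifest;
a reload reproduces predictions exactly.

Filter visualization performs gradient ascent on an all-zero 10-s input
chunk to maximize a chosen conv filter's mean activation (normalized
gradient steps, per-step L2 normalization of the chunk), then transforms
the optimized chunk with the Morse CWT. A filter with zero gradient from
the zero chunk is reported as dead.

## Problem sizes used by the shipped tests

The test and acceptance runs use scaled problem sizes chosen to exercise
the full chain at desk scale: micro-wire sessions of 4 channels × 30–120 s
at 10 kHz (the pipeline is rate-agnostic; 38.6 kHz changes only cost);
walking-task calibration over 200 null sessions with 6-s crossings and
0.4-s theta bursts (type-I error of the 16-channel permutation test,
verified during development at the 10-s/1-s defaults as well); decoder
experiments with 200-event sessions, 4 channels in 2 region branches,
stratified half splits, 30 epochs at batch size 8. Generator defaults keep
the full study conditions.

## Known limitations

- The ICA component auto-selection can pick a spike-dominated component
  when sessions contain no artifacts but dense spiking; the manual
  override exists for that case, and detection on artifact-free sessions
  is tested only on stationary noise.
- The zero-crossing phase tracker assumes one dominant band oscillation;
  nested or multi-component rhythms would need a quadrature tracker.
- The trained-on-noise decoder's threshold-0.5 F1 is a noisy statistic:
  run-level score offsets make single-run null F1 bimodal even when AUC
  is exactly 0.5; chance behaviour is therefore asserted on the mean over
  seeds.
- Morse-CWT coefficients are not numerically identical to any specific
  toolbox implementation; only peak locations and scaling laws are
  contractual.
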