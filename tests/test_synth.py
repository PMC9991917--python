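"""Synthetic session generators: determinism, counts, spectral structure."""

import numpy as np
import pytest

from neurostack import synth
from neurostack.core import CoreError
from neurostack.spectral import fft_power


class TestMicrowire:
    def test_seed_determinism(self):
        a, _ = synth.gen_microwire(n_channels=2, fs=5000, duration_s=2, seed=7)
        b, _ = synth.gen_microwire(n_channels=2, fs=5000, duration_s=2, seed=7)
        np.testing.assert_array_equal(a.data, b.data)

    def test_poisson_spike_count(self):
        units = [{"template": 0, "rate_hz": 10.0, "amplitude": 80.0, "channel": 0}]
        _, truth = synth.gen_microwire(n_channels=1, fs=10_000, duration_s=10,
                                       units=units, seed=3)
        n = truth.unit_spike_times["u0"].size
        assert abs(n - 100) <= 3 * np.sqrt(100)

    def test_line_component(self):
        kw = dict(n_channels=1, fs=2000, duration_s=8, units=[], theta_amp=0,
                  seed=5)
        with_line, _ = synth.gen_microwire(line_amp=5.0, **kw)
        without, _ = synth.gen_microwire(line_amp=0.0, **kw)

        def band(rec, lo, hi):
            f, p = fft_power(rec.data[0], rec.fs)
            return p[(f >= lo) & (f <= hi)].sum()

        assert band(with_line, 55, 65) > 5 * band(without, 55, 65)
        # without line, 55-65-Hz power is at background level (neighbor band)
        assert band(without, 55, 65) < 3 * band(without, 65, 75) + 1e-9

    def test_invalid_rate(self):
        units = [{"template": 0, "rate_hz": 0.0, "amplitude": 80.0}]
        with pytest.raises(CoreError):
            synth.gen_microwire(n_channels=1, fs=5000, duration_s=1, units=units)

    def test_one_over_f_slope(self, rng):
        x = synth.one_over_f_noise(2**16, 1000.0, 1.0, rng)
        f, p = fft_power(x, 1000.0)
        sel = (f > 1) & (f < 400)
        slope = np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0]
        assert -1.3 < slope < -0.7


class TestMotionArtifacts:
    def test_identity_when_disabled(self, microwire_session):
        rec, _ = microwire_session
        out, truth = synth.inject_motion_artifacts(rec, n_sharp=0, slow_amp=0.0)
        np.testing.assert_array_equal(out.data, rec.data)
        assert truth.artifact_intervals == []

    def test_sharp_bookkeeping(self, microwire_session):
        rec, _ = microwire_session
        out, truth = synth.inject_motion_artifacts(rec, n_sharp=20, seed=1)
        sharp = [iv for iv in truth.artifact_intervals if iv[2] == "sharp"]
        assert len(sharp) == 20
        # non-overlapping
        sharp.sort()
        assert all(s2 >= e1 for (_, e1, _), (s2, _, _) in zip(sharp, sharp[1:]))

    def test_sharp_exceeds_sd_multiple(self, microwire_session):
        rec, _ = microwire_session
        out, truth = synth.inject_motion_artifacts(
            rec, n_sharp=5, sharp_amp_sd_multiple=10, seed=2
        )
        sd = rec.data.std(axis=1)
        for s, e, _ in truth.artifact_intervals:
            seg = out.data[:, int(s * rec.fs): int(e * rec.fs)]
            peak = np.max(np.abs(seg - rec.data[:, int(s * rec.fs): int(e * rec.fs)]),
                          axis=1)
            assert np.all(peak > 0.8 * 10 * sd)  # mild per-channel gain spread

    def test_slow_power_below_band(self, microwire_session):
        rec, _ = microwire_session
        _, truth = synth.inject_motion_artifacts(
            rec, n_sharp=0, slow_amp=50.0, slow_band_hz=1.0, seed=3
        )
        slow = truth.slow_component[0]
        f, p = fft_power(slow, rec.fs)
        below = p[f < 1.0].sum()
        assert below / p.sum() > 0.99


class TestWalkSession:
    def test_crossing_counts(self):
        _, events, _ = synth.gen_walk_session(n_crossings=10, n_channels=2,
                                              crossing_duration_s=3, seed=0)
        assert len(events.of_kind("crossing_start")) == 10
        assert len(events.of_kind("crossing_end")) == 10

    def test_boundary_gain_modulates_truth_envelope(self):
        rec, events, truth = synth.gen_walk_session(
            n_crossings=4, crossing_duration_s=6, boundary_gain=2.0,
            n_channels=2, seed=1
        )
        fs = rec.fs
        starts = events.times_of("crossing_start")
        ends = events.times_of("crossing_end")
        b_mask = np.zeros(truth.theta_envelope.shape[1], dtype=bool)
        i_mask = np.zeros_like(b_mask)
        for t0, t1 in zip(starts, ends):
            a = t0 + (t1 - t0) / 3
            b = t0 + 2 * (t1 - t0) / 3
            i_mask[int(a * fs): int(b * fs)] = True
            b_mask[int(b * fs): int(t1 * fs)] = True
        # noiseless oscillator power: boundary > inner by construction
        env2 = truth.theta_envelope**2
        assert env2[:, b_mask].mean() > 1.5 * env2[:, i_mask].mean()

    def test_null_construction(self):
        rec, events, truth = synth.gen_walk_session(
            n_crossings=4, crossing_duration_s=6, boundary_gain=1.0,
            n_channels=2, seed=1
        )
        # gain array never deviates from the burst envelope
        assert truth.theta_envelope.max() <= 1.0 + 1e-9


class TestMemorySession:
    def test_event_counts_and_labels(self):
        _, events, truth = synth.gen_memory_session(n_blocks=9, words_per_block=10,
                                                    n_channels=2, seed=0)
        onsets = events.of_kind("word_onset")
        assert len(onsets) == 90
        assert all("remembered" in e.payload for e in onsets)
        blocks = {e.payload["block"] for e in onsets}
        assert len(blocks) == 9
        assert sum(1 for e in onsets if e.payload["block"] == 0) == 10
        assert truth.condition_labels == [e.payload["remembered"] for e in onsets]

    def test_null_effect_identical_envelope_distribution(self):
        rec, events, truth = synth.gen_memory_session(
            n_blocks=4, words_per_block=10, theta_effect=0.0, n_channels=2, seed=2
        )
        fs = rec.fs
        n_burst = int(2.0 * fs)
        powers = {True: [], False: []}
        for e in events.of_kind("word_onset"):
            i0 = int(round(e.time_s * fs))
            powers[e.payload["remembered"]].append(
                np.mean(truth.theta_envelope[i0: i0 + n_burst] ** 2)
            )
        assert np.mean(powers[True]) == pytest.approx(np.mean(powers[False]),
                                                      rel=0.05)


class TestStimSession:
    def test_protocol_counts(self):
        _, protocol, truth = synth.gen_stim_session(interburst_s=0.4, seed=0)
        assert protocol.n_bursts == 100
        assert len(truth.condition_labels) == 100 * 10  # pulses rendered

    def test_zero_gains_pure_noise(self):
        rec, _, _ = synth.gen_stim_session(
            amplitudes_ma=(1.0,), frequencies_hz=(100.0,), repeats=1,
            interburst_s=0.4, channel_gains=[0.0, 0.0], noise_sd=1.0, seed=0
        )
        assert np.max(np.abs(rec.data)) < 6.0  # Gaussian noise only


class TestThetaLFP:
    def test_phase_and_envelope_shapes(self):
        rec, truth = synth.gen_theta_lfp(duration_s=20, fs=500, seed=0)
        assert truth.theta_phase.size == rec.n_samples
        assert truth.theta_envelope.size == rec.n_samples
        assert 0 <= truth.theta_phase.min() and truth.theta_phase.max() < 2 * np.pi

    def test_snr_scaling(self):
        quiet, _ = synth.gen_theta_lfp(duration_s=30, snr=0.0, seed=1)
        loud, truth = synth.gen_theta_lfp(duration_s=30, snr=3.0, seed=1)
        on = truth.theta_envelope > 0.5
        assert loud.data[0, on].std() > 1.5 * quiet.data[0, on].std()
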