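"""Stimulation protocol grid, pulse rendering, detection and propagation
statistics."""

import numpy as np
import pytest

from neurostack import stim, synth
from neurostack.stim import Burst, ProtocolGridError, StimProtocol


class TestProtocolGrid:
    def test_defaults_valid(self):
        p = StimProtocol()
        assert p.n_bursts == 100

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"pulse_width_ms": 2.0},       # above range
            {"pulse_width_ms": 0.005},     # below range
            {"pulse_width_ms": 0.103},     # off the 10-us grid
            {"interphase_us": 200.0},      # above range
            {"interphase_us": 15.0, "pulse_width_ms": 0.1,
             "interphase_us": 15.0},       # off the 10-us grid
            {"polarity": "sideways"},
        ],
    )
    def test_off_grid_rejected(self, kwargs):
        with pytest.raises(ProtocolGridError):
            StimProtocol(**kwargs)

    def test_device_unit_amplitude_grid(self):
        StimProtocol(amplitudes_ma=(20, 40, 500), amplitude_unit="device")
        with pytest.raises(ProtocolGridError):
            StimProtocol(amplitudes_ma=(250,), amplitude_unit="device")


class TestSchedule:
    def test_count_law(self):
        for amps, freqs, reps in [((1, 2), (10, 20, 30), 2), ((0.5,), (60,), 7)]:
            p = StimProtocol(amplitudes_ma=amps, frequencies_hz=freqs,
                             repeats=reps)
            assert len(stim.schedule_bursts(p)) == len(amps) * len(freqs) * reps

    def test_inter_pulse_spacing(self):
        p = StimProtocol(amplitudes_ma=(1.0,), frequencies_hz=(100.0,), repeats=1)
        burst = stim.schedule_bursts(p)[0]
        np.testing.assert_allclose(np.diff(burst.pulse_times), 0.010)

    def test_onset_span(self):
        p = StimProtocol(amplitudes_ma=(1.0,), frequencies_hz=(60.0,), repeats=1,
                         pulses_per_burst=10)
        burst = stim.schedule_bursts(p)[0]
        assert burst.pulse_times[-1] - burst.pulse_times[0] == pytest.approx(9 / 60)

    def test_interburst_spacing(self):
        p = StimProtocol(amplitudes_ma=(1.0,), frequencies_hz=(60.0, 80.0),
                         repeats=1, interburst_s=16.67)
        bursts = stim.schedule_bursts(p)
        assert bursts[1].start_s - bursts[0].start_s == pytest.approx(16.67)


class TestRenderPulse:
    def test_charge_balance(self):
        w = stim.render_pulse(1.0, 1.28, 150.0, fs=6250.0)
        assert abs(w.sum()) < 1e-9 * np.abs(w).sum()

    def test_custom_equal_steps_is_rectangle(self):
        rect = stim.render_pulse(2.0, 0.64, 100.0, fs=50_000.0)
        custom = stim.render_pulse(2.0, 0.64, 100.0, fs=50_000.0,
                                   shape="custom_16_step",
                                   custom_steps=(1.0,) * 16)
        np.testing.assert_allclose(custom, rect)

    def test_amplitude_linearity(self):
        w1 = stim.render_pulse(1.0, 1.28, 150.0, fs=6250.0)
        w2 = stim.render_pulse(2.0, 1.28, 150.0, fs=6250.0)
        np.testing.assert_allclose(w2, 2.0 * w1)

    def test_polarity(self):
        a = stim.render_pulse(1.0, 1.0, 0.0, fs=10_000.0, polarity="anodic_first")
        c = stim.render_pulse(1.0, 1.0, 0.0, fs=10_000.0, polarity="cathodic_first")
        np.testing.assert_allclose(a, -c)


class TestDetection:
    def test_noiseless_recall_and_alignment(self):
        rec, protocol, _ = synth.gen_stim_session(
            interburst_s=0.4, noise_sd=0.0, gain_noise_sd=0.0,
            channel_gains=[1.0, 0.4], seed=0
        )
        tmpl = stim.render_pulse(1.0, protocol.pulse_width_ms,
                                 protocol.interphase_us, rec.fs)
        dets = stim.detect_pulses(rec, tmpl)
        sched = np.concatenate(
            [b.pulse_times for b in stim.schedule_bursts(protocol)]
        )
        for d in dets:
            assert d.pulse_times_s.size == 1000
            err = np.array([np.min(np.abs(sched - t)) for t in d.pulse_times_s])
            assert np.max(err) * rec.fs <= 1.0  # within one sample

    def test_zero_gain_channel_silent(self):
        rec, protocol, _ = synth.gen_stim_session(
            amplitudes_ma=(1.0,), frequencies_hz=(100.0,), repeats=2,
            interburst_s=0.4, noise_sd=0.5, channel_gains=[1.0, 0.0], seed=1
        )
        tmpl = stim.render_pulse(1.0, protocol.pulse_width_ms,
                                 protocol.interphase_us, rec.fs)
        dets = stim.detect_pulses(rec, tmpl)
        assert dets[0].pulse_times_s.size == 20
        assert dets[1].pulse_times_s.size == 0


class TestPropagationStats:
    def test_normalization_and_grouping(self):
        rec, protocol, _ = synth.gen_stim_session(
            interburst_s=0.4, noise_sd=0.5, gain_noise_sd=0.0,
            channel_gains=[1.0, 0.3], seed=2
        )
        tmpl = stim.render_pulse(1.0, protocol.pulse_width_ms,
                                 protocol.interphase_us, rec.fs)
        dets = stim.detect_pulses(rec, tmpl)
        df = stim.propagation_stats(dets, protocol)
        assert np.all(df.n_pulses == 40)  # 10 pulses x 4 repeats per condition
        assert df.mean_norm_power.max() <= 1.0
        top = max(d.normalized_power.max() for d in dets)
        assert top == pytest.approx(1.0)

    def test_noiseless_identical_pulses_zero_sd(self):
        rec, protocol, _ = synth.gen_stim_session(
            amplitudes_ma=(1.0,), frequencies_hz=(100.0,), repeats=2,
            interburst_s=0.4, noise_sd=0.0, gain_noise_sd=0.0,
            channel_gains=[1.0], seed=3
        )
        tmpl = stim.render_pulse(1.0, protocol.pulse_width_ms,
                                 protocol.interphase_us, rec.fs)
        df = stim.propagation_stats(stim.detect_pulses(rec, tmpl), protocol)
        assert np.all(df.sd_norm_power < 1e-12)

    def test_relative_sd_decreases_with_amplitude(self):
        # fixed additive noise: higher currents -> lower relative variability
        rec, protocol, _ = synth.gen_stim_session(
            interburst_s=0.4, noise_sd=3.0, gain_noise_sd=0.0,
            channel_gains=[0.8], seed=4
        )
        tmpl = stim.render_pulse(1.0, protocol.pulse_width_ms,
                                 protocol.interphase_us, rec.fs)
        df = stim.propagation_stats(stim.detect_pulses(rec, tmpl), protocol)
        rel = (
            df.assign(cv=df.sd_norm_power / df.mean_norm_power)
            .groupby("amplitude")["cv"].mean()
        )
        assert rel.loc[0.25] > rel.loc[1.25]
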