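"""Spike detection, clustering, acceptance rules and quality metrics."""

import numpy as np
import pytest

from neurostack import spikes, synth
from neurostack.core import Recording
from neurostack.spikes import UnitCluster


def make_cluster(times, waveform=None, n_wave=None):
    times = np.asarray(times, dtype=float)
    if waveform is None:
        waveform = synth.spike_template(0, 20_000.0)
    waves = np.tile(waveform, (times.size, 1))
    return UnitCluster("ch0", times, waves)


class TestDetection:
    def test_recall_on_synthetic_unit(self):
        units = [{"template": 0, "rate_hz": 10.0, "amplitude": 120.0,
                  "channel": 0}]
        rec, truth = synth.gen_microwire(n_channels=1, fs=20_000, duration_s=60,
                                         noise_sd=8.0, units=units, seed=5)
        dets = spikes.detect_spikes(rec, threshold_sd=5.0)
        det_times = np.array([t for t, _ in dets])
        gt = truth.unit_spike_times["u0"]
        recall = np.mean([np.min(np.abs(det_times - g)) < 5e-4 for g in gt])
        assert recall >= 0.9

    def test_false_rate_on_noise(self):
        rec, _ = synth.gen_microwire(n_channels=1, fs=20_000, duration_s=30,
                                     units=[], theta_amp=0, seed=6)
        dets = spikes.detect_spikes(rec, threshold_sd=5.0)
        assert len(dets) / 30.0 < 0.5

    def test_zero_signal(self):
        rec = Recording(np.zeros((1, 100_000)), 20_000.0, ["a"])
        assert spikes.detect_spikes(rec) == []


class TestClustering:
    def test_two_templates_recovered(self):
        units = [
            {"template": 0, "rate_hz": 6.0, "amplitude": 40.0, "channel": 0,
             "id": "small"},
            {"template": 1, "rate_hz": 6.0, "amplitude": 80.0, "channel": 0,
             "id": "big"},
        ]
        rec, truth = synth.gen_microwire(n_channels=1, fs=20_000, duration_s=60,
                                         noise_sd=3.0, units=units, seed=7)
        dets = spikes.detect_spikes(rec, threshold_sd=5.0)
        clusters = spikes.cluster_spikes(dets, seed=0)
        clusters = sorted(clusters, key=lambda c: -c.n_spikes)[:2]
        assert len(clusters) == 2
        for c in clusters:
            corrs = []
            for uid in ("small", "big"):
                tmpl = truth.unit_templates[uid]
                m = c.mean_waveform
                L = min(tmpl.size, m.size)
                # align template peak to snippet center
                pk_t = np.argmax(np.abs(tmpl))
                pk_m = np.argmax(np.abs(m))
                lo = min(pk_t, pk_m, 5)
                hi = min(tmpl.size - pk_t, m.size - pk_m)
                seg_t = tmpl[pk_t - lo: pk_t + hi]
                seg_m = m[pk_m - lo: pk_m + hi]
                corrs.append(np.corrcoef(seg_t, seg_m)[0, 1])
            assert max(corrs) > 0.95

    def test_single_template_dominant_cluster(self):
        units = [{"template": 0, "rate_hz": 8.0, "amplitude": 80.0, "channel": 0}]
        rec, truth = synth.gen_microwire(n_channels=1, fs=20_000, duration_s=60,
                                         noise_sd=4.0, units=units, seed=8)
        dets = spikes.detect_spikes(rec, threshold_sd=5.0)
        clusters = spikes.cluster_spikes(dets, seed=0)
        biggest = max(clusters, key=lambda c: c.n_spikes)
        assert biggest.n_spikes >= 0.9 * truth.unit_spike_times["u0"].size * 0.9

    def test_empty_detections(self):
        assert spikes.cluster_spikes([]) == []


class TestAcceptance:
    @pytest.mark.parametrize(
        "n_spikes,n_violations,expected",
        [(300, 2, True), (250, 0, False), (1000, 15, False), (251, 2, True),
         (1000, 10, True)],
    )
    def test_rule(self, n_spikes, n_violations, expected):
        # construct ISIs: violations at 2 ms, the rest at 10 ms
        isis = np.full(n_spikes - 1, 0.010)
        isis[:n_violations] = 0.002
        times = np.concatenate([[0.0], np.cumsum(isis)])
        c = make_cluster(times)
        assert c.n_isi_violations == n_violations
        assert spikes.accept_cluster(c) is expected

    def test_monotone_in_clean_spikes(self):
        # adding violation-free spikes never flips accepted -> rejected
        isis = np.full(260, 0.010)
        isis[:2] = 0.002
        times = np.concatenate([[0.0], np.cumsum(isis)])
        c = make_cluster(times)
        assert spikes.accept_cluster(c)
        extra = times[-1] + 0.010 + np.arange(200) * 0.010
        c2 = make_cluster(np.concatenate([times, extra]))
        assert spikes.accept_cluster(c2)


class TestFiringRate:
    def test_uniform_rate(self):
        times = np.linspace(0.05, 9.95, 100)
        rate = spikes.firing_rate(make_cluster(times), duration_s=10.0)
        assert rate.mean() == pytest.approx(10.0, rel=0.01)

    def test_count_conserved(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 10, 137))
        rate = spikes.firing_rate(make_cluster(times), duration_s=10.0)
        assert rate.sum() * 0.050 == pytest.approx(137, rel=1e-6)

    def test_empty_and_single(self):
        zero = spikes.firing_rate(make_cluster([]), duration_s=5.0)
        assert np.all(zero == 0)
        one = spikes.firing_rate(make_cluster([2.0]), duration_s=5.0)
        assert one.sum() * 0.050 == pytest.approx(1.0, rel=1e-6)


class TestQualityMetrics:
    def test_snr_formula(self):
        wave = np.zeros(30)
        wave[10] = -60.0
        c = make_cluster([1.0, 2.0], waveform=wave)
        assert spikes.unit_snr(c, noise_sd=4.0) == pytest.approx(5.0)
        assert spikes.unit_snr(make_cluster([1.0], waveform=np.zeros(30)), 4.0) == 0.0

    def test_snr_recovered_from_synthetic(self):
        units = [{"template": 0, "rate_hz": 8.0, "amplitude": 90.0, "channel": 0}]
        rec, truth = synth.gen_microwire(n_channels=1, fs=20_000, duration_s=60,
                                         noise_sd=5.0, units=units, seed=9)
        dets = spikes.detect_spikes(rec, threshold_sd=5.0)
        clusters = spikes.cluster_spikes(dets, seed=0)
        c = max(clusters, key=lambda c: c.n_spikes)
        from neurostack.core import FilterSpec, filter_array, robust_noise_sd
        band = filter_array(rec.data[0], FilterSpec("bandpass", (300.0, 3000.0)),
                            rec.fs)
        noise_sd = robust_noise_sd(band)
        snr = spikes.unit_snr(c, noise_sd)
        # analytic peak: the injected template after the same detection band
        tmpl = truth.unit_templates["u0"]
        padded = np.concatenate([np.zeros(2000), tmpl, np.zeros(2000)])
        peak = np.max(np.abs(
            filter_array(padded, FilterSpec("bandpass", (300.0, 3000.0)), rec.fs)
        ))
        assert snr == pytest.approx(peak / (3 * noise_sd), rel=0.10)

    def test_ari_formula(self):
        wave = synth.spike_template(0, 20_000.0) * 50
        times = np.arange(300) * 0.040
        before = [UnitCluster("ch0", times, np.tile(wave, (300, 1)))]
        after = [UnitCluster("ch0", times[:297], np.tile(wave, (297, 1)))]
        out = spikes.yield_and_ari(before, after, n_channels=16)
        assert out["ari_percent"] == pytest.approx(-1.0)

    def test_ari_zero_when_identical(self):
        wave = synth.spike_template(1, 20_000.0) * 50
        c = UnitCluster("ch0", np.linspace(0, 10, 300), np.tile(wave, (300, 1)))
        out = spikes.yield_and_ari([c], [c], n_channels=4)
        assert out["ari_percent"] == 0.0

    def test_end_to_end_yield_and_ari(self):
        # 2 units/channel at SNR >= 5: recovered yield within +-0.5
        # units/channel of truth; artifact removal changes matched accepted
        # units' spike counts by at most 5% (artifacts carry no spikes)
        from neurostack import artifacts

        rec, truth = synth.gen_microwire(n_channels=4, fs=10_000,
                                         duration_s=120, seed=3)
        dirty, _ = synth.inject_motion_artifacts(
            rec, n_sharp=30, sharp_amp_sd_multiple=10, seed=43
        )
        ivs, comp = artifacts.detect_sharp_transients(dirty, seed=0)
        cleaned, _ = artifacts.interpolate_intervals(dirty, ivs, comp)
        before, after = [], []
        for ch in range(rec.n_channels):
            before += spikes.cluster_spikes(
                spikes.detect_spikes(dirty, channel=ch, threshold_sd=5.0),
                seed=0, channel_id=rec.channel_ids[ch],
            )
            after += spikes.cluster_spikes(
                spikes.detect_spikes(cleaned, channel=ch, threshold_sd=5.0),
                seed=0, channel_id=rec.channel_ids[ch],
            )
        out = spikes.yield_and_ari(before, after, rec.n_channels)
        true_yield = len(truth.unit_spike_times) / rec.n_channels
        assert abs(out["yield"] - true_yield) <= 0.5
        assert abs(out["ari_percent"]) <= 5.0

    def test_yield_value(self):
        wave = synth.spike_template(0, 20_000.0) * 50
        accepted = [
            UnitCluster(f"ch{i}", np.arange(300) * 0.01, np.tile(wave, (300, 1)))
            for i in range(9)
        ]
        out = spikes.yield_and_ari([], accepted, n_channels=16)
        assert out["yield"] == pytest.approx(0.5625)
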