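"""Memory decoder: network gradients, windowing, balancing, metrics,
transfer-learning freeze contract, serialization and filter visualization."""

import numpy as np
import pytest

from neurostack import synth
from neurostack.core import CoreError, Event, EventStream, Recording
from neurostack.decoder import (
    balance_classes,
    decode_metrics,
    extract_windows,
    split_by_block,
    transfer_and_predict,
)
from neurostack.decoder.model import Branch, BranchDecoder, DecoderSpec
from neurostack.decoder.nn import bce_loss_and_grad
from neurostack.decoder.pipeline import visualize_filters

TINY = DecoderSpec(conv_filters=(3, 4), kernel=3, strides=(2, 2), pool=2,
                   lstm_units=5, lstm_dropout=0.0, lstm_recurrent_dropout=0.0,
                   dropout=0.0, dense_units=4, l2_penalty=1e-3, epochs=3,
                   batch_size=4)


class TestNetworkGradients:
    def test_backprop_matches_finite_differences(self, rng):
        model = BranchDecoder([2, 1], TINY, seed=1)
        X = rng.standard_normal((4, 40, 3))
        y = np.array([1.0, 0.0, 1.0, 0.0])

        def total_loss():
            loss, _ = bce_loss_and_grad(model.forward_logits(X), y)
            for br in model.branches:
                loss += br.conv1.l2_loss() + br.conv2.l2_loss()
            return loss + model.dense1.l2_loss() + model.dense2.l2_loss()

        params = model.params()
        for p in params:
            p.grad[...] = 0.0
        _, dlog = bce_loss_and_grad(model.forward_logits(X), y)
        model.backward(dlog)

        eps = 1e-6
        for p in params:
            flat, grad = p.value.ravel(), p.grad.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = total_loss()
                flat[i] = orig - eps
                lm = total_loss()
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(grad[i], rel=1e-4, abs=1e-7)

    def test_training_reduces_loss_on_separable_data(self, rng):
        model = BranchDecoder([2], TINY, seed=0)
        X = rng.standard_normal((40, 40, 2)) * 0.1
        y = (rng.random(40) < 0.5).astype(float)
        X[y == 1] += 0.8
        losses = model.fit(X, y, epochs=25, seed=0)
        assert losses[-1] < losses[0] * 0.7


class TestExtractWindows:
    def _session(self):
        return synth.gen_memory_session(n_blocks=3, words_per_block=10,
                                        n_channels=2, seed=1)

    def test_chunk_geometry(self):
        rec, events, _ = self._session()
        ds = extract_windows(rec, events)
        assert ds.chunks.shape == (30, 2500, 2)
        assert ds.weights.size == 2500
        assert ds.labels.size == 30

    def test_gaussian_weight_profile(self):
        rec, events, _ = self._session()
        ds = extract_windows(rec, events)
        onset_idx = int(5.0 * 250)
        assert ds.weights[onset_idx] == pytest.approx(1.0, abs=1e-3)
        at_sigma = int((5.0 + 2.5) * 250)
        assert ds.weights[at_sigma] == pytest.approx(np.exp(-0.5), rel=0.01)

    def test_edge_events_dropped_with_warning(self):
        fs = 250.0
        rec = Recording(np.random.default_rng(0).normal(size=(1, int(30 * fs))),
                        fs, ["a"])
        events = EventStream([
            Event(2.0, "word_onset", {"remembered": True}),   # too early
            Event(15.0, "word_onset", {"remembered": False}),
        ])
        with pytest.warns(UserWarning, match="dropped 1"):
            ds = extract_windows(rec, events)
        assert ds.n_events == 1

    def test_unlabelled_onset_rejected(self):
        rec = Recording(np.zeros((1, 5000)), 250.0, ["a"])
        events = EventStream([Event(10.0, "word_onset", {})])
        with pytest.raises(CoreError):
            extract_windows(rec, events)


class TestBalanceClasses:
    def _ds(self, n_pos, n_neg):
        rec, events, _ = synth.gen_memory_session(n_blocks=5, words_per_block=10,
                                                  n_channels=2, seed=2)
        ds = extract_windows(rec, events)
        labels = np.zeros(ds.n_events, dtype=bool)
        labels[:n_pos] = True
        ds.labels = labels
        return ds

    def test_majority_subsampled(self):
        ds = balance_classes(self._ds(30, 20), seed=0)
        assert ds.labels.sum() == 20
        assert (~ds.labels).sum() == 20

    def test_already_balanced_unchanged_counts(self):
        ds = balance_classes(self._ds(25, 25), seed=0)
        assert ds.labels.sum() == 25 and ds.n_events == 50

    def test_seed_determinism(self):
        a = balance_classes(self._ds(30, 20), seed=5)
        b = balance_classes(self._ds(30, 20), seed=5)
        np.testing.assert_array_equal(a.event_times, b.event_times)


class TestDecodeMetrics:
    def test_perfect_predictions(self):
        y = np.array([True, True, False, False])
        rep = decode_metrics(np.array([0.9, 0.8, 0.1, 0.2]), y)
        assert rep.f1 == 1.0 and rep.accuracy == 1.0 and rep.auc == 1.0

    def test_f1_formula_identity(self):
        # P = R = 0.69 -> F1 = 0.69; build a confusion matrix achieving it:
        # 69 TP, 31 FN, 31 FP -> P = 69/100, R = 69/100
        scores = np.concatenate([np.full(69, 0.9), np.full(31, 0.1),
                                 np.full(31, 0.9), np.full(69, 0.1)])
        labels = np.concatenate([np.ones(100, bool), np.zeros(100, bool)])
        rep = decode_metrics(scores, labels)
        assert rep.f1 == pytest.approx(0.69)

    def test_random_scores_chance_auc(self, rng):
        y = rng.random(10_000) < 0.5
        rep = decode_metrics(rng.random(10_000), y)
        assert rep.auc == pytest.approx(0.5, abs=0.02)

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import f1_score, roc_auc_score

        y = rng.random(500) < 0.4
        s = np.clip(rng.random(500) + 0.2 * y, 0, 1)
        rep = decode_metrics(s, y)
        assert rep.f1 == pytest.approx(f1_score(y, s > 0.5))
        assert rep.auc == pytest.approx(roc_auc_score(y, s), abs=1e-9)


class TestTransferLearning:
    def _blocks(self):
        rec, events, _ = synth.gen_memory_session(n_blocks=4, words_per_block=8,
                                                  n_channels=2, n_regions=1,
                                                  theta_effect=2.0, seed=3)
        ds = extract_windows(rec, events)
        return split_by_block(ds)

    def test_frozen_parameters_bit_identical(self):
        blocks = self._blocks()
        model = BranchDecoder([2], TINY, seed=0)
        before = [p.value.copy() for p in model.branch_params()]
        transfer_and_predict(model, blocks, n_train_blocks=2,
                             epochs_per_block=2, seed=0)
        after = [p.value for p in model.branch_params()]
        for b, a in zip(before, after):
            assert np.array_equal(b, a)

    def test_head_parameters_change(self):
        blocks = self._blocks()
        model = BranchDecoder([2], TINY, seed=0)
        before = [p.value.copy() for p in model.head_params()]
        transfer_and_predict(model, blocks, n_train_blocks=2,
                             epochs_per_block=2, seed=0)
        assert any(not np.array_equal(b, p.value)
                   for b, p in zip(before, model.head_params()))

    def test_serialize_reload_identical_predictions(self, tmp_path, rng):
        model = BranchDecoder([2, 1], TINY, seed=4)
        X = rng.standard_normal((6, 40, 3))
        ref = model.predict_proba(X)
        path = tmp_path / "model.json"
        model.save_json(path)
        clone = BranchDecoder.load_json(path)
        np.testing.assert_array_equal(clone.predict_proba(X), ref)


class TestVisualization:
    def test_dead_filter_flagged(self):
        model = BranchDecoder([1], TINY, seed=0)
        # zero the first conv completely: zero input + zero bias = dead
        model.branches[0].conv1.W.value[...] = 0.0
        model.branches[0].conv1.b.value[...] = 0.0
        out = visualize_filters(model, branch=0, conv_layer=1, filter_idx=0,
                                steps=5)
        assert out["dead"] is True
        assert out["tf_map"] is None

    def test_constructed_sine_filter_peaks_at_its_frequency(self):
        # one conv layer whose only filter is a 6-Hz sinusoidal kernel:
        # gradient ascent from zeros must produce a chunk whose wavelet
        # energy peaks within one grid step of 6 Hz
        fs = 250.0
        kernel_len = 125  # half a second
        spec = DecoderSpec(conv_filters=(1, 1), kernel=kernel_len,
                           strides=(1, 1), pool=2, lstm_units=3,
                           lstm_dropout=0.0, lstm_recurrent_dropout=0.0,
                           dropout=0.0, dense_units=2, l2_penalty=0.0)
        model = BranchDecoder([1], spec, seed=0)
        t = np.arange(kernel_len) / fs
        model.branches[0].conv1.W.value[:, 0] = np.sin(2 * np.pi * 6.0 * t)
        model.branches[0].conv1.b.value[:] = 0.01  # keep ReLU gradient alive
        out = visualize_filters(model, branch=0, conv_layer=0, filter_idx=0,
                                steps=30, step_size=0.5)
        assert not out["dead"]
        assert np.all(np.diff(out["activations"]) >= -1e-9)
        mean_power = out["tf_map"].mean(axis=0)
        peak = out["freqs_hz"][np.argmax(mean_power)]
        grid = out["freqs_hz"]
        step = np.argmin(np.abs(grid - peak)) - np.argmin(np.abs(grid - 6.0))
        assert abs(step) <= 1
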