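"""Branch decoder: per-region CNN1D x2 + LSTM feature extractors with a
shared fully connected head and binary classifier.

Each brain region's channel group is consumed by a structurally identical
branch (conv 32 filters, conv 64 filters, LSTM 64 units); branch outputs
(final LSTM states) are concatenated and passed through a dense head
(32 units, ReLU) and a 1-unit classifier.  Training minimizes binary
cross-entropy with RMSprop (learning rate 0.001); dropout 0.2 after conv
and dense layers, 0.1 on LSTM inputs with 0.5 recurrent dropout; L2 weight
penalty on conv and dense layers.  Transfer learning freezes the branch
(conv + LSTM) parameters and retrains only the dense head.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import (
    AvgPool1D,
    Conv1D,
    Dense,
    Dropout,
    LSTM,
    Param,
    ReLU,
    RMSProp,
    bce_loss_and_grad,
    sigmoid,
)


@dataclass
class DecoderSpec:
    conv_filters: tuple = (32, 64)
    kernel: int = 7
    strides: tuple = (2, 2)
    pool: int = 8
    lstm_units: int = 64
    lstm_dropout: float = 0.1
    lstm_recurrent_dropout: float = 0.5
    dropout: float = 0.2
    dense_units: int = 32
    l2_penalty: float = 1e-4
    learning_rate: float = 0.001
    batch_size: int = 512
    epochs: int = 30
    threshold: float = 0.5


class Branch:
    """One region's feature extractor: conv1 -> conv2 -> pool -> LSTM."""

    def __init__(self, n_channels: int, spec: DecoderSpec, rng: np.random.Generator):
        f1, f2 = spec.conv_filters
        s1, s2 = spec.strides
        self.conv1 = Conv1D(n_channels, f1, spec.kernel, s1, spec.l2_penalty, rng)
        self.relu1 = ReLU()
        self.drop1 = Dropout(spec.dropout)
        self.conv2 = Conv1D(f1, f2, spec.kernel, s2, spec.l2_penalty, rng)
        self.relu2 = ReLU()
        self.drop2 = Dropout(spec.dropout)
        self.pool = AvgPool1D(spec.pool)
        self.lstm = LSTM(f2, spec.lstm_units, spec.lstm_dropout,
                         spec.lstm_recurrent_dropout, rng)
        self.layers = [self.conv1, self.relu1, self.drop1, self.conv2,
                       self.relu2, self.drop2, self.pool, self.lstm]

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def conv_activations(self, x, upto: int):
        """Forward through conv stack only (inference mode), returning the
        activation of conv layer ``upto`` (0-based) after its ReLU."""
        convs = [(self.conv1, self.relu1), (self.conv2, self.relu2)]
        for j, (conv, relu) in enumerate(convs):
            x = relu.forward(conv.forward(x))
            if j == upto:
                return x
        raise ValueError(f"no conv layer {upto}")

    def conv_input_gradient(self, x, upto: int, filter_idx: int):
        """Gradient of the mean activation of one filter w.r.t. the input
        chunk (inference mode, no dropout)."""
        act = self.conv_activations(x, upto)
        dy = np.zeros_like(act)
        dy[:, :, filter_idx] = 1.0 / act.shape[1]
        convs = [self.conv1, self.relu1, self.conv2, self.relu2][: 2 * (upto + 1)]
        for p in self.params():
            p.grad[...] = 0.0
        for layer in reversed(convs):
            dy = layer.backward(dy)
        loss = float(act[:, :, filter_idx].mean())
        return loss, dy


class BranchDecoder:
    """Multi-branch decoder with concatenated LSTM states and a dense head."""

    def __init__(self, channels_per_region: list[int],
                 spec: DecoderSpec | None = None, seed: int = 0):
        self.spec = spec or DecoderSpec()
        self.channels_per_region = list(channels_per_region)
        rng = np.random.default_rng(seed)
        self.branches = [Branch(nc, self.spec, rng) for nc in channels_per_region]
        merged = self.spec.lstm_units * len(self.branches)
        self.head_drop = Dropout(self.spec.dropout)
        self.dense1 = Dense(merged, self.spec.dense_units, "relu",
                            self.spec.l2_penalty, rng)
        self.head_drop2 = Dropout(self.spec.dropout)
        self.dense2 = Dense(self.spec.dense_units, 1, "linear",
                            self.spec.l2_penalty, rng)

    # -- parameter groups ---------------------------------------------------
    def branch_params(self) -> list[Param]:
        return [p for br in self.branches for p in br.params()]

    def head_params(self) -> list[Param]:
        return self.dense1.params() + self.dense2.params()

    def params(self) -> list[Param]:
        return self.branch_params() + self.head_params()

    # -- forward / backward -------------------------------------------------
    def _split(self, X: np.ndarray) -> list[np.ndarray]:
        """Split (B, T, C_total) into per-region channel groups."""
        outs = []
        c0 = 0
        for nc in self.channels_per_region:
            outs.append(X[:, :, c0: c0 + nc])
            c0 += nc
        return outs

    def forward_logits(self, X: np.ndarray, train=False, rng=None) -> np.ndarray:
        states = [
            br.forward(xr, train=train, rng=rng)
            for br, xr in zip(self.branches, self._split(X))
        ]
        h = np.concatenate(states, axis=1)
        h = self.head_drop.forward(h, train=train, rng=rng)
        h = self.dense1.forward(h, train=train, rng=rng)
        h = self.head_drop2.forward(h, train=train, rng=rng)
        return self.dense2.forward(h, train=train, rng=rng)

    def backward(self, dlogits: np.ndarray, into_branches: bool = True) -> None:
        dh = self.dense2.backward(dlogits)
        dh = self.head_drop2.backward(dh)
        dh = self.dense1.backward(dh)
        dh = self.head_drop.backward(dh)
        if not into_branches:
            return
        H = self.spec.lstm_units
        for j, br in enumerate(self.branches):
            br.backward(dh[:, j * H: (j + 1) * H])

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        probs = []
        for i in range(0, X.shape[0], batch_size):
            logits = self.forward_logits(X[i: i + batch_size], train=False)
            probs.append(sigmoid(logits).reshape(-1))
        return np.concatenate(probs) if probs else np.empty(0)

    # -- training -----------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int | None = None,
        seed: int = 0,
        trainable: str = "all",
        optimizer: RMSProp | None = None,
        shuffle: bool = True,
    ) -> list[float]:
        """Mini-batch RMSprop training; returns the per-epoch loss curve.

        ``trainable='head'`` freezes branch (conv/LSTM) parameters —
        gradients are neither computed nor applied for them.
        """
        rng = np.random.default_rng(seed)
        epochs = self.spec.epochs if epochs is None else epochs
        params = self.params() if trainable == "all" else self.head_params()
        opt = optimizer or RMSProp(lr=self.spec.learning_rate)
        into_branches = trainable == "all"
        bs = min(self.spec.batch_size, X.shape[0])
        losses = []
        for _ in range(epochs):
            idx = rng.permutation(X.shape[0]) if shuffle else np.arange(X.shape[0])
            epoch_loss = 0.0
            n_batches = 0
            for i in range(0, X.shape[0], bs):
                sel = idx[i: i + bs]
                opt.zero_grad(params)
                logits = self.forward_logits(X[sel], train=True, rng=rng)
                loss, dlogits = bce_loss_and_grad(logits, y[sel])
                self.backward(dlogits, into_branches=into_branches)
                opt.step(params)
                epoch_loss += loss
                n_batches += 1
            losses.append(epoch_loss / max(n_batches, 1))
        return losses

    # -- serialization ------------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ValueError("weight count mismatch")
        for p, w in zip(params, weights):
            p.value = np.asarray(w, dtype=np.float64).reshape(p.value.shape)

    def save_json(self, path) -> None:
        """Portable JSON weight manifest (architecture + all parameters)."""
        payload = {
            "channels_per_region": self.channels_per_region,
            "spec": self.spec.__dict__,
            "weights": [p.value.tolist() for p in self.params()],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load_json(cls, path) -> "BranchDecoder":
        payload = json.loads(Path(path).read_text())
        spec_d = payload["spec"]
        for key in ("conv_filters", "strides"):
            spec_d[key] = tuple(spec_d[key])
        model = cls(payload["channels_per_region"], DecoderSpec(**spec_d))
        model.set_weights([np.array(w) for w in payload["weights"]])
        return model
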