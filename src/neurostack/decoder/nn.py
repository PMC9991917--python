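"""Minimal neural-network layers with manual backpropagation.

Implements exactly the pieces the memory decoder needs — 1-D convolution,
ReLU, average pooling, (variational) dropout, an LSTM returning its final
state, dense layers, a sigmoid/binary-cross-entropy head and an RMSprop
optimizer — in numpy, with analytically derived gradients (verified by
finite differences in the test suite).  Shapes are channels-last:
``(batch, time, channels)``.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name


def glorot(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x, train: bool = False, rng: np.random.Generator | None = None):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


class Conv1D(Layer):
    """1-D convolution (valid padding) with stride, channels-last."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 7, stride: int = 1,
                 l2: float = 0.0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.kernel, self.stride, self.l2 = kernel, stride, l2
        self.in_ch, self.out_ch = in_ch, out_ch
        self.W = Param(
            glorot(rng, (kernel * in_ch, out_ch), kernel * in_ch, out_ch), "conv_W"
        )
        self.b = Param(np.zeros(out_ch), "conv_b")

    def params(self):
        return [self.W, self.b]

    def out_len(self, T: int) -> int:
        return (T - self.kernel) // self.stride + 1

    def forward(self, x, train=False, rng=None):
        # y[b,t,o] = sum_j x[b, s*t + j] @ W_j  — accumulated over kernel
        # taps via strided views, so no im2col buffer is materialized
        B, T, C = x.shape
        k, s = self.kernel, self.stride
        T_out = self.out_len(T)
        W3 = self.W.value.reshape(k, C, self.out_ch)
        y = np.broadcast_to(self.b.value, (B, T_out, self.out_ch)).copy()
        for j in range(k):
            y += x[:, j: j + s * T_out: s] @ W3[j]
        self._x = x
        return y

    def backward(self, dy):
        x = self._x
        B, T, C = x.shape
        k, s = self.kernel, self.stride
        T_out = dy.shape[1]
        W3 = self.W.value.reshape(k, C, self.out_ch)
        dW3 = self.W.grad.reshape(k, C, self.out_ch)
        dx = np.zeros_like(x)
        dy2 = dy.reshape(-1, self.out_ch)
        for j in range(k):
            xj = x[:, j: j + s * T_out: s]
            dW3[j] += xj.reshape(-1, C).T @ dy2
            dx[:, j: j + s * T_out: s] += dy @ W3[j].T
        self.W.grad += 2.0 * self.l2 * self.W.value
        self.b.grad += dy.sum(axis=(0, 1))
        return dx

    def l2_loss(self) -> float:
        return self.l2 * float(np.sum(self.W.value**2))


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class AvgPool1D(Layer):
    def __init__(self, pool: int):
        self.pool = pool

    def forward(self, x, train=False, rng=None):
        B, T, C = x.shape
        p = self.pool
        T_out = T // p
        self._shape = (B, T, C)
        return x[:, : T_out * p].reshape(B, T_out, p, C).mean(axis=2)

    def backward(self, dy):
        B, T, C = self._shape
        p = self.pool
        dx = np.zeros((B, T, C))
        T_out = dy.shape[1]
        dx[:, : T_out * p] = np.repeat(dy / p, p, axis=1)
        return dx


class Dropout(Layer):
    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class LSTM(Layer):
    """LSTM consuming a sequence and emitting its final hidden state.

    Variational dropout: one input mask and one recurrent mask per forward
    pass, shared across timesteps.
    """

    def __init__(self, in_dim: int, units: int, dropout: float = 0.1,
                 recurrent_dropout: float = 0.5,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_dim, self.units = in_dim, units
        self.dropout, self.recurrent_dropout = dropout, recurrent_dropout
        H = units
        self.Wx = Param(glorot(rng, (in_dim, 4 * H), in_dim, 4 * H), "lstm_Wx")
        self.Wh = Param(glorot(rng, (H, 4 * H), H, 4 * H), "lstm_Wh")
        b = np.zeros(4 * H)
        b[H: 2 * H] = 1.0  # forget-gate bias
        self.b = Param(b, "lstm_b")

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x, train=False, rng=None):
        B, T, D = x.shape
        H = self.units
        if train and self.dropout > 0:
            keep = 1.0 - self.dropout
            in_mask = (rng.random((B, 1, D)) < keep) / keep
            x = x * in_mask
        else:
            in_mask = None
        if train and self.recurrent_dropout > 0:
            keep = 1.0 - self.recurrent_dropout
            self._rmask = (rng.random((B, H)) < keep) / keep
        else:
            self._rmask = None
        self._in_mask = in_mask

        h = np.zeros((B, H))
        c = np.zeros((B, H))
        I = np.empty((T, B, H)); F = np.empty((T, B, H))
        G = np.empty((T, B, H)); O = np.empty((T, B, H))
        Cs = np.empty((T, B, H)); Cprev = np.empty((T, B, H))
        Hm = np.empty((T, B, H))
        for t in range(T):
            hm = h * self._rmask if self._rmask is not None else h
            z = x[:, t] @ self.Wx.value + hm @ self.Wh.value + self.b.value
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H: 2 * H])
            g = np.tanh(z[:, 2 * H: 3 * H])
            o = _sigmoid(z[:, 3 * H:])
            Cprev[t] = c
            c = f * c + i * g
            h = o * np.tanh(c)
            I[t], F[t], G[t], O[t], Cs[t], Hm[t] = i, f, g, o, c, hm
        self._cache = (x, I, F, G, O, Cs, Cprev, Hm)
        return h

    def backward(self, dh_last):
        x, I, F, G, O, Cs, Cprev, Hm = self._cache
        B, T, D = x.shape
        H = self.units
        dx = np.zeros_like(x)
        dh = dh_last.copy()
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            tc = np.tanh(Cs[t])
            do = dh * tc
            dc = dc + dh * O[t] * (1 - tc**2)
            di = dc * G[t]
            dg = dc * I[t]
            df = dc * Cprev[t]
            dz = np.concatenate(
                [
                    di * I[t] * (1 - I[t]),
                    df * F[t] * (1 - F[t]),
                    dg * (1 - G[t] ** 2),
                    do * O[t] * (1 - O[t]),
                ],
                axis=1,
            )
            self.Wx.grad += x[:, t].T @ dz
            self.Wh.grad += Hm[t].T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.value.T
            dh = dz @ self.Wh.value.T
            if self._rmask is not None:
                dh = dh * self._rmask
            dc = dc * F[t]
        if self._in_mask is not None:
            dx = dx * self._in_mask
        return dx


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, activation: str = "linear",
                 l2: float = 0.0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.activation, self.l2 = activation, l2
        self.W = Param(glorot(rng, (in_dim, out_dim), in_dim, out_dim), "dense_W")
        self.b = Param(np.zeros(out_dim), "dense_b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False, rng=None):
        self._x = x
        z = x @ self.W.value + self.b.value
        if self.activation == "relu":
            self._mask = z > 0
            return z * self._mask
        return z

    def backward(self, dy):
        if self.activation == "relu":
            dy = dy * self._mask
        self.W.grad += self._x.T @ dy + 2.0 * self.l2 * self.W.value
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T

    def l2_loss(self) -> float:
        return self.l2 * float(np.sum(self.W.value**2))


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def sigmoid(z):
    return _sigmoid(np.asarray(z, dtype=float))


def bce_loss_and_grad(logits: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy on logits; returns (loss, dlogits)."""
    logits = logits.reshape(-1)
    y = y.reshape(-1).astype(float)
    p = _sigmoid(logits)
    eps = 1e-12
    loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    dlogits = (p - y) / y.size
    return loss, dlogits.reshape(-1, 1)


class RMSProp:
    """Root-mean-square propagation (rho 0.9, eps 1e-7)."""

    def __init__(self, lr: float = 0.001, rho: float = 0.9, eps: float = 1e-7):
        self.lr, self.rho, self.eps = lr, rho, eps
        self._cache: dict[int, np.ndarray] = {}

    def step(self, params: list[Param]) -> None:
        for p in params:
            c = self._cache.setdefault(id(p), np.zeros_like(p.value))
            c *= self.rho
            c += (1 - self.rho) * p.grad**2
            p.value -= self.lr * p.grad / (np.sqrt(c) + self.eps)

    def zero_grad(self, params: list[Param]) -> None:
        for p in params:
            p.grad[...] = 0.0
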