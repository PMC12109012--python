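"""Minimal numpy neural-network layers with explicit backpropagation.

Implements exactly the pieces the fall-confirmation classifier needs —
Conv1D (valid padding), ReLU, batch normalization, max pooling, LSTM with
standard gate semantics, inverted dropout, and a dense head — plus Adam and a
numerically stable binary cross-entropy on logits. Layers operate on float64
arrays shaped (batch, time, channels); every gradient is derived by hand and
checked against central finite differences in the test suite.

Weight initialization is Glorot uniform (orthodox for both conv and recurrent
kernels here; the LSTM forget-gate bias starts at 1). All randomness (init,
dropout masks) flows through explicitly passed generators, so training is
bit-reproducible given a seed.
"""

from __future__ import annotations

from typing import Dict, List, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base layer: parameter dicts plus forward/backward passes."""

    def __init__(self):
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """1-D convolution, valid padding, stride 1: (B, L, Cin) → (B, L−K+1, F)."""

    def __init__(self, in_channels: int, filters: int, kernel_size: int, rng: np.random.Generator):
        super().__init__()
        self.kernel_size = kernel_size
        fan_in = kernel_size * in_channels
        fan_out = kernel_size * filters
        self.params["W"] = _glorot_uniform(rng, (kernel_size, in_channels, filters), fan_in, fan_out)
        self.params["b"] = np.zeros(filters)

    def forward(self, x, training=False):
        self._windows = sliding_window_view(x, self.kernel_size, axis=1)  # (B, Lout, C, K)
        return np.einsum("blck,kcf->blf", self._windows, self.params["W"]) + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = np.einsum("blck,blf->kcf", self._windows, dy)
        self.grads["b"] = dy.sum(axis=(0, 1))
        dwin = np.einsum("blf,kcf->blck", dy, self.params["W"])
        B, Lout, C, K = dwin.shape
        dx = np.zeros((B, Lout + K - 1, C))
        for k in range(K):
            dx[:, k : k + Lout, :] += dwin[:, :, :, k]
        return dx


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class BatchNorm(Layer):
    """Per-channel normalization over batch and time axes.

    Running statistics (exponential moving average, momentum 0.9) are used at
    inference; eps = 1e-3.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, training=False):
        if training:
            axes = tuple(range(x.ndim - 1))
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._n = x.size // x.shape[-1]
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._training = training
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        self.grads["gamma"] = (dy * self._xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        if not self._training:
            return dy * self.params["gamma"] / self._std
        n = self._n
        g = self.params["gamma"]
        dsum = dy.sum(axis=axes)
        dxhat_sum = (dy * self._xhat).sum(axis=axes)
        return (g / (n * self._std)) * (n * dy - dsum - self._xhat * dxhat_sum)


class MaxPool1D(Layer):
    """Non-overlapping temporal max pooling; a trailing remainder is dropped."""

    def __init__(self, pool_size: int = 2):
        super().__init__()
        self.pool_size = pool_size

    def forward(self, x, training=False):
        B, L, C = x.shape
        p = self.pool_size
        Lout = L // p
        blocks = x[:, : Lout * p, :].reshape(B, Lout, p, C)
        self._argmax = blocks.argmax(axis=2)
        self._in_shape = x.shape
        return blocks.max(axis=2)

    def backward(self, dy):
        B, Lout, C = dy.shape
        p = self.pool_size
        dx = np.zeros(self._in_shape)
        dblocks = dx[:, : Lout * p, :].reshape(B, Lout, p, C)
        bi, li, ci = np.ogrid[:B, :Lout, :C]
        dblocks[bi, li, self._argmax, ci] = dy
        dx[:, : Lout * p, :] = dblocks.reshape(B, Lout * p, C)
        return dx


class Dropout(Layer):
    """Inverted dropout on the incoming activations (identity at inference)."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class LSTM(Layer):
    """Single LSTM layer with the standard gate recurrence.

    Gates (per step t, input z_t, previous hidden state r_{t-1}, cell s_{t-1}):
    forget f = σ(·), input i = σ(·), candidate s̃ = tanh(·), memory
    s = f⊙s_{t-1} + i⊙s̃, output o = σ(·), hidden r = o⊙tanh(s).
    Returns the full hidden sequence or only the final state.
    """

    def __init__(
        self,
        in_dim: int,
        units: int,
        rng: np.random.Generator,
        return_sequences: bool = False,
    ):
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences
        H = units
        self.params["W"] = _glorot_uniform(rng, (in_dim, 4 * H), in_dim, H)
        self.params["U"] = _glorot_uniform(rng, (H, 4 * H), H, H)
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0  # forget-gate bias starts open
        self.params["b"] = b

    def forward(self, x, training=False):
        B, T, D = x.shape
        H = self.units
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._x = x
        self._cache = []
        hs = np.empty((B, T, H))
        for t in range(T):
            z = x[:, t, :] @ W + h @ U + b
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = sigmoid(z[:, 3 * H :])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t, :] = h
            self._cache.append((i, f, g, o, c_prev, h_prev, tc))
        self._hs = hs
        return hs if self.return_sequences else h

    def backward(self, dy):
        x = self._x
        B, T, D = x.shape
        H = self.units
        W, U = self.params["W"], self.params["U"]
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros(4 * H)
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, h_prev, tc = self._cache[t]
            dh = dh_next + (dy[:, t, :] if self.return_sequences else 0)
            if not self.return_sequences and t == T - 1:
                dh = dh + dy
            do = dh * tc
            dc = dc_next + dh * o * (1 - tc * tc)
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dW += x[:, t, :].T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ W.T
            dh_next = dz @ U.T
            dc_next = dc * f
        self.grads["W"], self.grads["U"], self.grads["b"] = dW, dU, db
        return dx


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, units: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = _glorot_uniform(rng, (in_dim, units), in_dim, units)
        self.params["b"] = np.zeros(units)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Sequential:
    """Plain layer chain with shared forward/backward plumbing."""

    def __init__(self, layers: List[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        """Yield (layer_index, name, array) for every trainable parameter."""
        for li, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                yield li, name, value

    def n_parameters(self) -> int:
        return sum(v.size for _, _, v in self.parameters())

    def get_weights(self) -> Dict[str, np.ndarray]:
        out = {}
        for li, name, value in self.parameters():
            out[f"{li}.{name}"] = value
        for li, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm):
                out[f"{li}.running_mean"] = layer.running_mean
                out[f"{li}.running_var"] = layer.running_var
        return out

    def set_weights(self, weights: Dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = np.array(weights[f"{li}.{name}"], dtype=float)
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.array(weights[f"{li}.running_mean"], dtype=float)
                layer.running_var = np.array(weights[f"{li}.running_var"], dtype=float)


class Adam:
    """Adam optimizer over a Sequential's parameters."""

    def __init__(
        self,
        model: Sequential,
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ):
        self.model = model
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {f"{li}.{name}": np.zeros_like(v) for li, name, v in model.parameters()}
        self.v = {k: np.zeros_like(m) for k, m in self.m.items()}

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for li, name, param in self.model.parameters():
            key = f"{li}.{name}"
            grad = self.model.layers[li].grads[name]
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * grad
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * grad * grad
            mhat = self.m[key] / b1t
            vhat = self.v[key] / b2t
            param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_with_logits(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy computed stably on logits."""
    z = logits.ravel()
    y = np.asarray(labels, dtype=float).ravel()
    # softplus(z) - y*z, with softplus evaluated stably
    loss = np.maximum(z, 0) - y * z + np.log1p(np.exp(-np.abs(z)))
    return float(loss.mean())


def bce_with_logits_grad(logits: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """d(mean BCE)/d(logits): (σ(z) − y)/N, shaped like ``logits``."""
    y = np.asarray(labels, dtype=float).reshape(logits.shape)
    return (sigmoid(logits) - y) / logits.shape[0]
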