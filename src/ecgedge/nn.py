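"""Minimal seeded NumPy neural-network engine.

Implements exactly the pieces the two classifier architectures need —
dense layers, 1-D convolution and average pooling with 'same' padding,
inverted dropout, the swish activation (x * sigmoid(x)), a softmax
cross-entropy head and the Adam optimizer.  Forward/backward passes are
plain array code; all randomness (init, shuffling, dropout) flows from a
single numpy Generator so training is a pure function of its seed.

Also provides fake-quantization utilities used to emulate 8-bit inference:
a value x is mapped through the affine int8 grid

    q  = clip(round(x / scale) + zero_point, 0, 255)
    xq = (q - zero_point) * scale

with per-tensor scale/zero-point taken from observed min/max.
"""

from __future__ import annotations

import numpy as np


def swish(x: np.ndarray) -> np.ndarray:
    return x / (1.0 + np.exp(-x))


def swish_grad(x: np.ndarray) -> np.ndarray:
    s = 1.0 / (1.0 + np.exp(-x))
    return s * (1.0 + x * (1.0 - s))


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Fake quantization


def quant_params(lo: float, hi: float) -> tuple:
    """Per-tensor affine uint8 scale/zero-point covering [lo, hi] (and 0)."""
    lo, hi = min(lo, 0.0), max(hi, 0.0)
    if hi == lo:
        return 1.0, 0
    scale = (hi - lo) / 255.0
    zp = int(round(-lo / scale))
    return scale, int(np.clip(zp, 0, 255))


def fake_quant(x: np.ndarray, scale: float, zp: int) -> np.ndarray:
    q = np.clip(np.round(x / scale) + zp, 0, 255)
    return (q - zp) * scale


# ---------------------------------------------------------------------------
# Layers


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train: bool, rng):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.w + self.b

    def backward(self, g):
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.w.T


class Swish(Layer):
    def forward(self, x, train, rng):
        self._x = x
        return swish(x)

    def backward(self, g):
        return g * swish_grad(self._x)


class Dropout(Layer):
    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Reshape(Layer):
    """(B, rows*cols) -> (B, rows, cols); time rows, channel columns."""

    def __init__(self, rows: int):
        super().__init__()
        self.rows = rows

    def forward(self, x, train, rng):
        b, n = x.shape
        if n % self.rows:
            raise ValueError(f"input length {n} not divisible by {self.rows} reshape rows")
        self._shape = x.shape
        return x.reshape(b, self.rows, n // self.rows)

    def backward(self, g):
        return g.reshape(self._shape)


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Conv1D(Layer):
    """1-D convolution along the time axis, 'same' zero padding, stride 1.

    Input (B, T, C_in) -> output (B, T, filters).  Implemented as im2col
    + matrix multiply; weights (k*C_in, filters).
    """

    def __init__(self, c_in: int, filters: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.k, self.c_in, self.filters = kernel, c_in, filters
        fan_in, fan_out = kernel * c_in, kernel * filters
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.w = rng.uniform(-limit, limit, size=(kernel * c_in, filters))
        self.b = np.zeros(filters)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def _im2col(self, x):
        b, t, c = x.shape
        pl = (self.k - 1) // 2
        xp = np.pad(x, ((0, 0), (pl, self.k - 1 - pl), (0, 0)))
        cols = np.empty((b, t, self.k * c))
        for j in range(self.k):
            cols[:, :, j * c : (j + 1) * c] = xp[:, j : j + t, :]
        return cols

    def forward(self, x, train, rng):
        self._xshape = x.shape
        self._cols = self._im2col(x)
        return self._cols @ self.w + self.b

    def backward(self, g):
        b, t, c = self._xshape
        self.grads[0][...] = np.einsum("btk,btf->kf", self._cols, g)
        self.grads[1][...] = g.sum(axis=(0, 1))
        gcols = g @ self.w.T  # (b, t, k*c)
        pl = (self.k - 1) // 2
        gx = np.zeros((b, t + self.k - 1, c))
        for j in range(self.k):
            gx[:, j : j + t, :] += gcols[:, :, j * c : (j + 1) * c]
        return gx[:, pl : pl + t, :]


class AvgPool1D(Layer):
    """Average pooling, pool = stride = 2, 'same' padding.

    Output length ceil(T/2); a trailing window shorter than the pool size
    averages over the samples actually present.
    """

    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x, train, rng):
        b, t, c = x.shape
        self._t = t
        t_out = -(-t // self.pool)
        out = np.empty((b, t_out, c))
        self._counts = np.empty(t_out)
        for i in range(t_out):
            seg = x[:, i * self.pool : min((i + 1) * self.pool, t), :]
            self._counts[i] = seg.shape[1]
            out[:, i, :] = seg.mean(axis=1)
        return out

    def backward(self, g):
        b, t_out, c = g.shape
        gx = np.zeros((b, self._t, c))
        for i in range(t_out):
            lo, hi = i * self.pool, min((i + 1) * self.pool, self._t)
            gx[:, lo:hi, :] += g[:, i : i + 1, :] / self._counts[i]
        return gx


# ---------------------------------------------------------------------------
# Network


class Sequential:
    """A feed-forward stack ending in logits; softmax lives in the loss."""

    def __init__(self, layers: list):
        self.layers = layers
        self.quantized = False
        self.quant_meta = None  # list of per-layer activation (scale, zp)

    def parameters(self):
        for layer in self.layers:
            yield from zip(layer.params, layer.grads)

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        if self.quantized and not train:
            return self._forward_quantized(x)
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def _forward_quantized(self, x):
        for layer, act_q in zip(self.layers, self.quant_meta):
            x = layer.forward(x, False, None)
            if act_q is not None:
                x = fake_quant(x, *act_q)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return softmax(self.forward(x, train=False))

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)


class Adam:
    def __init__(self, model: Sequential, lr: float, beta1=0.9, beta2=0.999, eps=1e-7):
        self.model, self.lr = model, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in model.parameters()]
        self.v = [np.zeros_like(p) for p, _ in model.parameters()]
        self.t = 0

    def step(self):
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for i, (p, g) in enumerate(self.model.parameters()):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            p -= self.lr * (self.m[i] / b1c) / (np.sqrt(self.v[i] / b2c) + self.eps)


def cross_entropy(logits: np.ndarray, onehot: np.ndarray) -> tuple:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    loss = float(-(onehot * np.log(np.clip(p, 1e-12, None))).sum(axis=1).mean())
    return loss, (p - onehot) / logits.shape[0]
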