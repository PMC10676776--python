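"""Minimal NumPy neural-network layers with reverse-mode gradients.

Everything operates on float32 arrays shaped (batch, tokens, channels) for
the sequence layers and (batch, features) after flattening.  Each layer
caches what its backward pass needs during forward(); backward() consumes the
upstream gradient, accumulates parameter gradients and returns the gradient
with respect to its input.  Adam is implemented directly.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def elu(x, alpha: float = 1.0):
    """Exponential linear unit: x for x > 0, alpha*(e^x - 1) otherwise."""
    x = np.asarray(x)
    return np.where(x > 0, x, alpha * np.expm1(np.minimum(x, 0.0)))


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def scaled_dot_attention(q: np.ndarray, k: np.ndarray, v: np.ndarray) -> np.ndarray:
    """softmax(Q K^T / sqrt(d_k)) V for 2-D (or batched 3-D) inputs.

    Rows of the softmax are non-negative and sum to one; d_k is taken from
    the trailing axis of q/k.
    """
    q, k, v = (np.asarray(a, dtype=np.float64) for a in (q, k, v))
    if q.shape[-1] != k.shape[-1]:
        raise ValueError(f"q and k disagree on d_k: {q.shape[-1]} vs {k.shape[-1]}")
    if k.shape[-2] != v.shape[-2]:
        raise ValueError(f"k and v disagree on m: {k.shape[-2]} vs {v.shape[-2]}")
    d_k = q.shape[-1]
    scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(d_k)
    return softmax(scores, axis=-1) @ v


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        if alpha <= 0:
            raise ValueError("elu alpha must be positive")
        self.alpha = alpha

    def forward(self, x, train):
        if train:
            self._x = x
        return elu(x, self.alpha).astype(DTYPE)

    def backward(self, g):
        x = self._x
        return (g * np.where(x > 0, 1.0, self.alpha * np.exp(np.minimum(x, 0.0)))).astype(DTYPE)


class SelfAttention(Layer):
    """Single-head scaled dot-product self-attention over the token axis."""

    def __init__(self, in_ch: int, d_k: int, d_v: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(in_ch)
        self.wq = Param(rng.normal(0.0, s, (in_ch, d_k)))
        self.wk = Param(rng.normal(0.0, s, (in_ch, d_k)))
        self.wv = Param(rng.normal(0.0, s, (in_ch, d_v)))
        self.d_k = d_k

    def params(self):
        return [self.wq, self.wk, self.wv]

    def forward(self, x, train):
        q = x @ self.wq.value
        k = x @ self.wk.value
        v = x @ self.wv.value
        p = softmax(q @ k.transpose(0, 2, 1) / np.sqrt(self.d_k), axis=-1).astype(DTYPE)
        if train:
            self._cache = (x, q, k, v, p)
        return p @ v

    def backward(self, g):
        x, q, k, v, p = self._cache
        dv = p.transpose(0, 2, 1) @ g
        dp = g @ v.transpose(0, 2, 1)
        ds = (p * (dp - (dp * p).sum(axis=-1, keepdims=True))) / DTYPE(np.sqrt(self.d_k))
        dq = ds @ k
        dk = ds.transpose(0, 2, 1) @ q
        self.wq.grad += np.einsum("blc,bld->cd", x, dq, dtype=DTYPE)
        self.wk.grad += np.einsum("blc,bld->cd", x, dk, dtype=DTYPE)
        self.wv.grad += np.einsum("blc,bld->cd", x, dv, dtype=DTYPE)
        return dq @ self.wq.value.T + dk @ self.wk.value.T + dv @ self.wv.value.T


class Conv1d(Layer):
    """1-D convolution over tokens with same-padding (odd kernel)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0 or kernel < 1:
            raise ValueError("conv kernel must be odd and positive")
        s = np.sqrt(2.0 / (in_ch * kernel))
        self.w = Param(rng.normal(0.0, s, (kernel, in_ch, out_ch)))
        self.b = Param(np.zeros(out_ch))
        self.kernel = kernel

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        pad = self.kernel // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        L = x.shape[1]
        y = np.zeros((x.shape[0], L, self.w.value.shape[2]), dtype=DTYPE)
        for j in range(self.kernel):
            y += xp[:, j : j + L, :] @ self.w.value[j]
        y += self.b.value
        if train:
            self._xp, self._L = xp, L
        return y

    def backward(self, g):
        xp, L = self._xp, self._L
        pad = self.kernel // 2
        self.b.grad += g.sum(axis=(0, 1))
        dxp = np.zeros_like(xp)
        for j in range(self.kernel):
            self.w.grad[j] += np.einsum("blc,blo->co", xp[:, j : j + L, :], g, dtype=DTYPE)
            dxp[:, j : j + L, :] += g @ self.w.value[j].T
        return dxp[:, pad : pad + L, :]


class AvgPool1d(Layer):
    def __init__(self, size: int):
        self.size = size

    def forward(self, x, train):
        B, L, C = x.shape
        if L % self.size:
            raise ValueError(f"token length {L} not divisible by pool size {self.size}")
        return x.reshape(B, L // self.size, self.size, C).mean(axis=2)

    def backward(self, g):
        return np.repeat(g, self.size, axis=1) / DTYPE(self.size)


class Upsample1d(Layer):
    """Nearest-neighbour up-sampling along the token axis."""

    def __init__(self, factor: int):
        self.factor = factor

    def forward(self, x, train):
        return np.repeat(x, self.factor, axis=1)

    def backward(self, g):
        B, L, C = g.shape
        return g.reshape(B, L // self.factor, self.factor, C).sum(axis=2)


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        s = np.sqrt(2.0 / d_in)
        self.w = Param(rng.normal(0.0, s, (d_in, d_out)))
        self.b = Param(np.zeros(d_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, g):
        self.w.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.w.value.T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


class Adam:
    def __init__(self, params: list[Param], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad**2 - v)
            p.value -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(DTYPE)
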