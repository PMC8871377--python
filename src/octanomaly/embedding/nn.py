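"""Minimal dependency-free neural-network layers with reverse-mode gradients.

Just enough machinery for the compact convolutional backbone used here:
stride-1 same-padding convolutions (expressed as k*k shifted matrix
products), 2x2 max pooling, average-pool downsampling, dense layers and
Adam.  Arrays are NCHW float64; each layer caches what its backward pass
needs, so forward(train=True) -> backward must be called in pairs.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class: parameter-free identity."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (or k x k) stride-1 convolution with same padding, He init."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.k = k
        self.pad = k // 2
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.standard_normal((c_out, c_in, k, k)) * scale
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        out = np.zeros((n, self.W.shape[0], h, w))
        for i in range(self.k):
            for j in range(self.k):
                # out[n,f,:,:] += sum_c xp[n,c,i:i+h,j:j+w] * W[f,c,i,j]
                out += np.einsum(
                    "nchw,fc->nfhw", xp[:, :, i : i + h, j : j + w], self.W[:, :, i, j]
                )
        out += self.b[None, :, None, None]
        if train:
            self._xp = xp
        return out

    def backward(self, g):
        xp = self._xp
        assert xp is not None, "forward(train=True) must precede backward"
        n, c, hp, wp = xp.shape
        h, w = g.shape[2], g.shape[3]
        self.db[...] = g.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        for i in range(self.k):
            for j in range(self.k):
                self.dW[:, :, i, j] = np.einsum("nfhw,nchw->fc", g, xp[:, :, i : i + h, j : j + w])
                dxp[:, :, i : i + h, j : j + w] += np.einsum("nfhw,fc->nchw", g, self.W[:, :, i, j])
        p = self.pad
        self._xp = None
        return dxp[:, :, p : hp - p, p : wp - p]


class ReLU(Layer):
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, g):
        return g * self._mask


class MaxPool2(Layer):
    """2x2 max pooling; odd trailing rows/columns are cropped."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : 2 * h2, : 2 * w2]
        blocks = xc.reshape(n, c, h2, 2, w2, 2)
        out = blocks.max(axis=(3, 5))
        if train:
            self._shape = x.shape
            self._mask = blocks == out[:, :, :, None, :, None]
            # break ties: keep only the first max in each 2x2 block
            flat = self._mask.reshape(n, c, h2, w2, 4)
            first = np.cumsum(flat, axis=-1) == 1
            self._mask = (flat & first).reshape(n, c, h2, 2, w2, 2)
        return out

    def backward(self, g):
        n, c, h, w = self._shape
        h2, w2 = h // 2, w // 2
        gx = (self._mask * g[:, :, :, None, :, None]).reshape(n, c, 2 * h2, 2 * w2)
        if (h, w) != (2 * h2, 2 * w2):
            out = np.zeros(self._shape)
            out[:, :, : 2 * h2, : 2 * w2] = gx
            return out
        return gx


class AvgPool(Layer):
    """k x k average-pool downsampling (the cheap input reducer)."""

    def __init__(self, k: int):
        self.k = k

    def forward(self, x, train=False):
        if self.k == 1:
            return x
        n, c, h, w = x.shape
        k = self.k
        hk, wk = h // k, w // k
        self._shape = x.shape
        return x[:, :, : hk * k, : wk * k].reshape(n, c, hk, k, wk, k).mean(axis=(3, 5))

    def backward(self, g):
        if self.k == 1:
            return g
        n, c, h, w = self._shape
        k = self.k
        out = np.zeros(self._shape)
        up = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        out[:, :, : up.shape[2], : up.shape[3]] = up
        return out


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        rng = rng or np.random.default_rng()
        if zero_init:
            self.W = np.zeros((d_in, d_out))
        else:
            self.W = rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)
        self.b = np.zeros(d_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.dW[...] = self._x.T @ g
        self.db[...] = g.sum(axis=0)
        return g @ self.W.T


class Adam:
    """Adam over an explicit (param, grad) registry; grads are overwritten in place."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params, self.grad_refs = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, self.grad_refs, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
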