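"""Minimal deterministic CNN building blocks (numpy, CPU, float32).

Just enough machinery for the frame classifier: valid 3x3 convolution
(im2col + BLAS matmul), ReLU, 2x2 max-pooling, a dense head, softmax
cross-entropy and Adam. Everything is seeded through
``numpy.random.Generator``, so identical seeds give identical
initialization, shuffling and therefore training trajectories under
single-threaded execution.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H-k+1, W-k+1, C*k*k) patch matrix."""
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # N,C,oh,ow,k,k
    win = win.transpose(0, 2, 3, 1, 4, 5)              # N,oh,ow,C,k,k
    n, oh, ow = win.shape[:3]
    return np.ascontiguousarray(win).reshape(n, oh, ow, -1)


class Layer:
    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def describe(self) -> tuple:
        raise NotImplementedError


class Conv2D(Layer):
    """Valid convolution, He-normal init."""

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_channels * kernel * kernel))
        self.W = (rng.standard_normal(
            (filters, in_channels, kernel, kernel)) * scale).astype(np.float32)
        self.b = np.zeros(filters, dtype=np.float32)
        self.k = kernel
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x if train else None
        cols = _im2col(x, self.k)
        if train:
            self._cols = cols
        wmat = self.W.reshape(self.W.shape[0], -1).T  # C*k*k, F
        out = cols @ wmat + self.b
        return out.transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, f, oh, ow = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, f)
        self.grads[0][...] = (
            dflat.T @ self._cols.reshape(-1, self._cols.shape[-1])
        ).reshape(self.W.shape)
        self.grads[1][...] = dflat.sum(axis=0)
        # dx = full correlation of dout with the flipped, transposed kernel
        pad = self.k - 1
        dpad = np.pad(dout, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        wt = self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # C,F,k,k
        cols = _im2col(dpad, self.k)
        dx = cols @ wt.reshape(wt.shape[0], -1).T
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))

    def describe(self) -> tuple:
        return ("conv", self.W.shape[0], (self.k, self.k))


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def describe(self) -> tuple:
        return ("relu",)


class MaxPool2x2(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        x = x[:, :, :h2 * 2, :w2 * 2]
        tiles = x.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
        tiles = tiles.reshape(n, c, h2, w2, 4)
        if train:
            self._shape = (n, c, h, w)
            self._arg = tiles.argmax(axis=-1)
        return tiles.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        h2, w2 = dout.shape[2], dout.shape[3]
        dtiles = np.zeros((n, c, h2, w2, 4), dtype=dout.dtype)
        np.put_along_axis(dtiles, self._arg[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, c, h, w), dtype=dout.dtype)
        dx[:, :, :h2 * 2, :w2 * 2] = (
            dtiles.reshape(n, c, h2, w2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h2 * 2, w2 * 2)
        )
        return dx

    def describe(self) -> tuple:
        return ("maxpool", (2, 2))


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)

    def describe(self) -> tuple:
        return ("flatten",)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T

    def describe(self) -> tuple:
        return ("dense", self.W.shape[1])


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray,
                       labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    grad = p.astype(np.float32)
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / np.float32(n)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def describe(self) -> list[tuple]:
        return [layer.describe() for layer in self.layers]


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= (lr_t * m / (np.sqrt(v) + self.eps)).astype(p.dtype)
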