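"""Minimal convolutional network with manual backprop (numpy only).

The detection models in this package are deliberately small: a stack of
3x3 convolutions with ReLU and 2x2 max-pooling (>= 2 downsampling
stages), global average pooling, and one or more fully connected heads.
At the patch sizes used here (64x64 arrow patches, 32x32 region patches)
training a few thousand steps takes seconds on one CPU, so a full deep
learning framework is unnecessary; forward and backward passes are
written out explicitly with im2col-based convolutions.

All parameter initialization and minibatch shuffling flow through a
single ``numpy.random.Generator``, which makes training bit-reproducible
for a fixed seed.
"""

from __future__ import annotations

import hashlib

import numpy as np


# --------------------------------------------------------------------------
# im2col helpers
# --------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, pad: int) -> tuple[np.ndarray, tuple]:
    """(N,C,H,W) -> (N*H*W, C*k*k) column matrix for stride-1 conv."""
    N, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, shape=(N, C, H, W, k, k),
        strides=(s[0], s[1], s[2], s[3], s[2], s[3]),
    )
    cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(N * H * W, C * k * k)
    return np.ascontiguousarray(cols), (N, C, H, W)


def _col2im(dcols: np.ndarray, shape: tuple, k: int, pad: int) -> np.ndarray:
    N, C, H, W = shape
    dxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(N, H, W, C, k, k)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + H, j:j + W] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dxp[:, :, pad:pad + H, pad:pad + W]


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------

class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv3x3(Layer):
    """3x3 same-padding convolution, stride 1, He-initialized."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 9
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, 3, 3)).astype(np.float64)
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        cols, self._shape = _im2col(x, 3, 1)
        self._cols = cols
        N, C, H, W = self._shape
        out = cols @ self.W.reshape(self.W.shape[0], -1).T + self.b
        return out.reshape(N, H, W, -1).transpose(0, 3, 1, 2)

    def backward(self, dy):
        N, C, H, W = self._shape
        dy2 = dy.transpose(0, 2, 3, 1).reshape(-1, self.W.shape[0])
        self.dW[...] = (dy2.T @ self._cols).reshape(self.W.shape)
        self.db[...] = dy2.sum(axis=0)
        dcols = dy2 @ self.W.reshape(self.W.shape[0], -1)
        return _col2im(dcols, self._shape, 3, 1)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x):
        self._m = x > 0
        return x * self._m

    def backward(self, dy):
        return dy * self._m


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (input dims must be even)."""

    def forward(self, x):
        N, C, H, W = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        # break ties deterministically: keep only the first max per window
        flat = self._mask.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4)
        first = np.cumsum(flat, axis=-1) == 1
        self._mask = (flat & first).reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._shape = x.shape
        return out

    def backward(self, dy):
        N, C, H, W = self._shape
        dx = self._mask * dy[:, :, :, None, :, None]
        return dx.reshape(N, C, H, W)


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        N, C, H, W = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (H * W)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]


def conv_backbone(channels: tuple[int, ...], rng: np.random.Generator) -> Sequential:
    """Conv-ReLU-pool stack ending in global average pooling."""
    layers: list[Layer] = []
    c_in = 1
    for c in channels:
        layers += [Conv3x3(c_in, c, rng), ReLU(), MaxPool2()]
        c_in = c
    layers.append(GlobalAvgPool())
    return Sequential(layers)


# --------------------------------------------------------------------------
# losses (logit-space, numerically stable)
# --------------------------------------------------------------------------

def sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def bce_with_logits(z, y):
    """Mean binary cross-entropy; returns (loss, dL/dz)."""
    z, y = np.asarray(z, float).ravel(), np.asarray(y, float).ravel()
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    dz = (sigmoid(z) - y) / z.size
    return float(loss.mean()), dz


def ce_with_logits(z, y, mask=None):
    """Masked mean cross-entropy over rows; returns (loss, dL/dz).

    Rows where ``mask`` is False contribute neither loss nor gradient.
    """
    z = np.asarray(z, float)
    y = np.asarray(y, int)
    n = z.shape[0]
    if mask is None:
        mask = np.ones(n, dtype=bool)
    p = softmax(z)
    denom = max(int(mask.sum()), 1)
    idx = np.arange(n)
    losses = -np.log(np.clip(p[idx, y], 1e-300, None))
    loss = float((losses * mask).sum() / denom)
    dz = p.copy()
    dz[idx, y] -= 1.0
    dz *= (mask[:, None] / denom)
    return loss, dz


# --------------------------------------------------------------------------
# optimizers
# --------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mh = m / (1 - self.b1 ** self.t)
            vh = v / (1 - self.b2 ** self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


class SGD:
    def __init__(self, params, lr=1e-3, momentum=0.9):
        self.params = params
        self.lr, self.mom = lr, momentum
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads):
        for p, g, v in zip(self.params, grads, self.v):
            v[...] = self.mom * v + g
            p -= self.lr * v


def params_hash(params) -> str:
    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p, dtype=np.float64).tobytes())
    return h.hexdigest()


def save_params(path, params) -> None:
    np.savez(path, **{f"p{i}": p for i, p in enumerate(params)})


def load_params_into(path, params) -> None:
    data = np.load(path)
    for i, p in enumerate(params):
        p[...] = data[f"p{i}"]
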