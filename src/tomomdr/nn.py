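"""A compact CPU neural-network core on numpy.

Provides exactly the pieces the package's learned components need: 2D
convolution (stride 1 or 2, 'same' padding), ReLU, global average pooling,
dense layers, MSE / binary-cross-entropy losses and an Adam optimizer, with
manual backpropagation throughout (including gradients with respect to the
*input*, used by the adversarial training option). Everything is
deterministic given a seed.

Array layout is NCHW. All layers expose ``forward(x)`` / ``backward(gout)``
(backward returns the gradient with respect to the layer input and
accumulates parameter gradients) and a ``params()`` list.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Conv2d", "ReLU", "GlobalAvgPool", "GlobalAvgMaxPool",
    "Dense", "Sequential",
    "Adam", "mse_loss", "bce_with_logits_loss", "sigmoid", "softplus",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Conv2d:
    """3x3 (or kxk) convolution, 'same' zero padding, stride 1 or 2."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd ('same' padding)")
        rng = rng or np.random.default_rng(0)
        self.k, self.stride = k, stride
        self.w = Param(_he_init(rng, (c_out, c_in, k, k), c_in * k * k))
        self.b = Param(np.zeros(c_out))
        self._x_padded = None
        self._x_shape = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        out = np.zeros((n, self.w.value.shape[0], ho, wo))
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s]
                out += np.einsum("oc,nchw->nohw", self.w.value[:, :, ki, kj],
                                 xs, optimize=True)
        out += self.b.value[None, :, None, None]
        self._x_padded, self._x_shape = xp, x.shape
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xp = self._x_padded
        n, c, hp, wp = xp.shape
        k, s, p = self.k, self.stride, self.k // 2
        ho, wo = gout.shape[2], gout.shape[3]
        dxp = np.zeros_like(xp)
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s]
                self.w.grad[:, :, ki, kj] += np.einsum(
                    "nohw,nchw->oc", gout, xs, optimize=True)
                dxp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += np.einsum(
                    "oc,nohw->nchw", self.w.value[:, :, ki, kj], gout,
                    optimize=True)
        self.b.grad += gout.sum(axis=(0, 2, 3))
        h, w = self._x_shape[2], self._x_shape[3]
        return dxp[:, :, p:p + h, p:p + w]


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class GlobalAvgPool:
    """(N, C, H, W) -> (N, C); makes the heads input-size agnostic."""

    def __init__(self):
        self._hw = None

    def params(self):
        return []

    def forward(self, x):
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, gout):
        h, w = self._hw
        return np.broadcast_to(gout[:, :, None, None] / (h * w),
                               gout.shape + (h, w)).copy()


class GlobalAvgMaxPool:
    """(N, C, H, W) -> (N, 2C): concatenated spatial mean and maximum.

    The max path keeps sparse, high-contrast signals (a few bright pixels)
    visible in the pooled features, which plain average pooling dilutes by
    1/(H*W)."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x):
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)
        idx = flat.argmax(axis=2)
        self._cache = (x.shape, idx)
        return np.concatenate([x.mean(axis=(2, 3)),
                               np.take_along_axis(flat, idx[:, :, None],
                                                  axis=2)[:, :, 0]], axis=1)

    def backward(self, gout):
        (n, c, h, w), idx = self._cache
        g_avg = gout[:, :c]
        g_max = gout[:, c:]
        dx = np.broadcast_to(g_avg[:, :, None, None] / (h * w),
                             (n, c, h, w)).copy()
        dflat = dx.reshape(n, c, h * w)
        np.put_along_axis(dflat, idx[:, :, None],
                          np.take_along_axis(dflat, idx[:, :, None], axis=2)
                          + g_max[:, :, None], axis=2)
        return dflat.reshape(n, c, h, w)


class Dense:
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(_he_init(rng, (n_in, n_out), n_in))
        self.b = Param(np.zeros(n_out))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, gout):
        self.w.grad += self._x.T @ gout
        self.b.grad += gout.sum(axis=0)
        return gout @ self.w.value.T


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    __call__ = forward

    def backward(self, gout):
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def get_weights(self):
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights):
        own = self.params()
        if len(own) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(own, weights):
            if p.value.shape != w.shape:
                raise ValueError(
                    f"weight shape mismatch: {p.value.shape} vs {w.shape}")
            p.value[...] = w


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mh = m / (1 - b1**self.t)
            vh = v / (1 - b2**self.t)
            p.value -= self.lr * mh / (np.sqrt(vh) + self.eps)


def sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softplus(x):
    return np.logaddexp(0.0, x)


def mse_loss(pred, target):
    """Mean squared error and gradient w.r.t. pred."""
    diff = pred - target
    n = diff.size
    return float(np.mean(diff**2)), 2.0 * diff / n


def bce_with_logits_loss(logits, labels):
    """Numerically stable binary cross entropy; gradient w.r.t. logits."""
    z, y = logits, labels
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.logaddexp(0, -np.abs(z))))
    return loss, (sigmoid(z) - y) / z.size
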