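"""Differentiable layers (channels-last layout: images are N x H x W x C)."""

from __future__ import annotations

import numpy as np


def relu(x):
    """Rectifier: x for x > 0, 0 otherwise."""
    return np.maximum(x, 0.0)


def sigmoid(x):
    """Numerically stable logistic 1 / (1 + exp(-x))."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Param:
    """A trainable array together with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self):
        return []

    def init(self, rng):  # noqa: B027 - optional hook
        pass

    def forward(self, x, training=False):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (by default) same-padding, stride-1 convolution.

    Implemented as k*k shifted broadcast matmuls over the padded input —
    mathematically identical to im2col but without the large gather.
    """

    def __init__(self, in_channels, out_channels, ksize=3):
        if ksize % 2 != 1:
            raise ValueError("ksize must be odd for same padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.ksize = ksize
        self.W = Param(np.zeros((ksize, ksize, in_channels, out_channels)))
        self.b = Param(np.zeros(out_channels))

    def init(self, rng):
        fan_in = self.ksize * self.ksize * self.in_channels
        self.W.value = rng.normal(0.0, np.sqrt(2.0 / fan_in), self.W.value.shape)
        self.b.value = np.zeros(self.out_channels)

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        k, p = self.ksize, self.ksize // 2
        n, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        out = np.broadcast_to(self.b.value, (n, h, w, self.out_channels)).copy()
        for i in range(k):
            for j in range(k):
                out += xp[:, i : i + h, j : j + w, :] @ self.W.value[i, j]
        if training:
            self._xp = xp
            self._in_shape = x.shape
        return out

    def backward(self, grad):
        k, p = self.ksize, self.ksize // 2
        n, h, w, c = self._in_shape
        self.b.grad += grad.sum(axis=(0, 1, 2))
        dxp = np.zeros_like(self._xp)
        for i in range(k):
            for j in range(k):
                xs = self._xp[:, i : i + h, j : j + w, :]
                self.W.grad[i, j] += np.tensordot(
                    xs, grad, axes=([0, 1, 2], [0, 1, 2])
                )
                dxp[:, i : i + h, j : j + w, :] += grad @ self.W.value[i, j].T
        self._xp = None
        return dxp[:, p : p + h, p : p + w, :]


class BatchNorm(Layer):
    """Batch normalisation over all axes but the last (feature) axis."""

    def __init__(self, num_features, momentum=0.9, eps=1e-5):
        self.num_features = num_features
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(num_features))
        self.beta = Param(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
            self._xhat = (x - mean) / np.sqrt(var + self.eps)
            self._std = np.sqrt(var + self.eps)
            out = self.gamma.value * self._xhat + self.beta.value
        else:
            # folded affine form of (x - rm) / sqrt(rv + eps) * gamma + beta
            a = self.gamma.value / np.sqrt(self.running_var + self.eps)
            out = x * a + (self.beta.value - self.running_mean * a)
        return out

    def backward(self, grad):
        axes = tuple(range(grad.ndim - 1))
        m = np.prod([grad.shape[a] for a in axes])
        self.gamma.grad += (grad * self._xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = self.gamma.value * grad
        dx = (
            g
            - g.mean(axis=axes)
            - self._xhat * (g * self._xhat).sum(axis=axes) / m
        ) / self._std
        self._xhat = None
        return dx


class MaxPool2D(Layer):
    """2x2, stride-2 max pooling. H and W must be even."""

    def __init__(self, size=2):
        if size != 2:
            raise ValueError("only 2x2 pooling is supported")
        self.size = 2

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"pooling needs even spatial dims, got {h}x{w}")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        xt = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
        idx = xt.argmax(axis=-1)
        out = np.take_along_axis(xt, idx[..., None], axis=-1)[..., 0]
        if training:
            self._idx = idx
            self._in_shape = x.shape
        return out

    def backward(self, grad):
        n, h, w, c = self._in_shape
        dxt = np.zeros((n, h // 2, w // 2, c, 4))
        np.put_along_axis(dxt, self._idx[..., None], grad[..., None], axis=-1)
        dx = (
            dxt.reshape(n, h // 2, w // 2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h, w, c)
        )
        self._idx = None
        return dx


class Flatten(Layer):
    def forward(self, x, training=False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, in_features, out_features):
        self.in_features = in_features
        self.out_features = out_features
        self.W = Param(np.zeros((in_features, out_features)))
        self.b = Param(np.zeros(out_features))

    def init(self, rng):
        self.W.value = rng.normal(
            0.0, np.sqrt(2.0 / self.in_features), self.W.value.shape
        )
        self.b.value = np.zeros(self.out_features)

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        if training:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        dx = grad @ self.W.value.T
        self._x = None
        return dx


class ReLU(Layer):
    def forward(self, x, training=False):
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad):
        dx = grad * self._mask
        self._mask = None
        return dx
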