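"""Neural-network layers with explicit forward/backward passes.

Each layer stores its trainable arrays in ``self.params`` and the matching
gradients (populated by ``backward``) in ``self.grads``.  ``forward`` caches
whatever the backward pass needs; layers are stateful between the two
calls, which is fine for plain minibatch training.

Image tensors flow channels-last, shape (n, height, width, channels): the
convolution is then a sum of nine shifted matrix products over the
contiguous channel axis, which is far faster in numpy than an explicit
im2col.  Compute dtype follows the parameter dtype (float32 by default for
speed; float64 for e.g. finite-difference checks).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "LeakyReLU",
    "Dropout",
    "MaxPool2",
    "Flatten",
    "Dense",
]


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, *, train=False, rng=None):  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """kxk same-padding convolution, stride 1, channels-last."""

    def __init__(self, in_channels, out_channels, kernel=3, rng=None,
                 dtype=np.float32, needs_input_grad=True):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.k = kernel
        self.pad = kernel // 2
        self.needs_input_grad = needs_input_grad
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = in_channels * kernel * kernel
        rng = rng or np.random.default_rng()
        # weights indexed (ki, kj, c_in, c_out)
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(kernel, kernel, in_channels, out_channels)
        ).astype(dtype)
        self.params["b"] = np.zeros(out_channels, dtype=dtype)

    def forward(self, x, *, train=False, rng=None):
        n, h, w, c = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        W = self.params["W"]
        out = np.zeros((n, h, w, self.out_channels), dtype=x.dtype)
        for i in range(self.k):
            for j in range(self.k):
                out += xp[:, i : i + h, j : j + w, :] @ W[i, j]
        out += self.params["b"]
        self._cache = (xp, (n, h, w, c))
        return out

    def backward(self, dout):
        xp, (n, h, w, c) = self._cache
        W = self.params["W"]
        p = self.pad
        dW = np.empty_like(W)
        g2 = dout.reshape(-1, self.out_channels)
        dxp = np.zeros_like(xp) if self.needs_input_grad else None
        for i in range(self.k):
            for j in range(self.k):
                xs = xp[:, i : i + h, j : j + w, :].reshape(-1, c)
                dW[i, j] = xs.T @ g2
                if self.needs_input_grad:
                    dxp[:, i : i + h, j : j + w, :] += dout @ W[i, j].T
        self.grads["W"] = dW
        self.grads["b"] = g2.sum(axis=0)
        if not self.needs_input_grad:
            return None
        return dxp[:, p : p + h, p : p + w, :]


class BatchNorm2d(Layer):
    """Per-channel batch normalization (channels-last) with running stats."""

    def __init__(self, channels, momentum=0.1, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x, *, train=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, train)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout):
        xhat, inv, train = self._cache
        axes = tuple(range(dout.ndim - 1))
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        scale = self.params["gamma"] * inv
        if not train:
            return dout * scale
        m = np.prod([dout.shape[a] for a in axes])
        mean_d = dout.mean(axis=axes)
        mean_dx = (dout * xhat).sum(axis=axes) / m
        return scale * (dout - mean_d - xhat * mean_dx)


class LeakyReLU(Layer):
    def __init__(self, slope=0.01):
        super().__init__()
        self.slope = slope

    def forward(self, x, *, train=False, rng=None):
        # one multiply per pass: cache the per-element slope factor
        self._factor = np.where(x >= 0, x.dtype.type(1.0), x.dtype.type(self.slope))
        return x * self._factor

    def backward(self, dout):
        return dout * self._factor


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, p=0.3):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p

    def forward(self, x, *, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        u = rng.random(x.shape, dtype=np.float32)
        self._mask = (u >= self.p).astype(x.dtype)
        self._mask *= x.dtype.type(1.0 / (1.0 - self.p))
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2, channels-last; ties share the gradient."""

    def forward(self, x, *, train=False, rng=None):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x2 pooling")
        x6 = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = x6.max(axis=(2, 4))
        mask = x6 == out[:, :, None, :, None, :]
        self._cache = (mask, mask.sum(axis=(2, 4), keepdims=True), x.shape)
        return out

    def backward(self, dout):
        mask, counts, (n, h, w, c) = self._cache
        d6 = mask * (dout[:, :, None, :, None, :] / counts)
        return d6.reshape(n, h, w, c)


class Flatten(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)
        ).astype(dtype)
        self.params["b"] = np.zeros(n_out, dtype=dtype)

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T
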