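"""Layers: 3D convolution (im2col), batch norm, pooling, linear, Adam.

Tensors are ``(batch, channels, x, y, z)`` float32. All convolutions are
stride-1 with zero 'same' padding; odd kernel edges only.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import ConfigurationError


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, D, H, W) -> (B * D*H*W, C * k^3) patch matrix (zero padded)."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    # (B, C, D, H, W, k, k, k) -> (B, D, H, W, C, k, k, k)
    win = win.transpose(0, 2, 3, 4, 1, 5, 6, 7)
    b, d, h, w = win.shape[:4]
    return np.ascontiguousarray(win).reshape(b * d * h * w, -1)


class Conv3d:
    """Stride-1 'same' 3D convolution with bias."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ConfigurationError(f"kernel edge must be odd, got {kernel}")
        self.cin, self.cout, self.k = in_channels, out_channels, kernel
        fan_in = in_channels * kernel ** 3
        self.W = (rng.standard_normal((out_channels, fan_in))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, d, h, w = x.shape
        cols = _im2col(x, self.k)
        out = cols @ self.W.T + self.b
        if train:
            self._cols, self._shape = cols, x.shape
        return out.reshape(b, d, h, w, self.cout).transpose(0, 4, 1, 2, 3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, co, d, h, w = dout.shape
        do = np.ascontiguousarray(dout.transpose(0, 2, 3, 4, 1)).reshape(-1, co)
        self.dW[...] = do.T @ self._cols
        self.db[...] = do.sum(axis=0)
        # dx = 'full' correlation of dout with channel-transposed, flipped W
        Wt = self.W.reshape(self.cout, self.cin, self.k, self.k, self.k)
        Wt = Wt[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)  # (Cin, Cout, k,k,k)
        Wt = np.ascontiguousarray(Wt).reshape(self.cin, -1)
        cols_d = _im2col(dout, self.k)
        dx = (cols_d @ Wt.T).reshape(b, d, h, w, self.cin).transpose(0, 4, 1, 2, 3)
        self._cols = None
        return dx

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class BatchNorm3d:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.2, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    @staticmethod
    def _stats_axes(x):
        return (0, 2, 3, 4)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = self._stats_axes(x)
        shape = (1, -1, 1, 1, 1)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu.reshape(shape)) * inv_std.reshape(shape)
        if train:
            self._cache = (xhat, inv_std)
        return self.gamma.reshape(shape) * xhat + self.beta.reshape(shape)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        axes = self._stats_axes(dout)
        shape = (1, -1, 1, 1, 1)
        n = dout.size / dout.shape[1]
        self.dgamma[...] = (dout * xhat).sum(axis=axes)
        self.dbeta[...] = dout.sum(axis=axes)
        dxhat = dout * self.gamma.reshape(shape)
        dx = (dxhat - dxhat.mean(axis=axes).reshape(shape)
              - xhat * (dxhat * xhat).mean(axis=axes).reshape(shape))
        return dx * inv_std.reshape(shape) * np.float32(1.0)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x, train: bool = False):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        dx = dout * self._mask
        self._mask = None
        return dx

    def params(self):
        return []


class AvgPool3d:
    """Non-overlapping average pooling by an integer factor (default 2)."""

    def __init__(self, factor: int = 2):
        self.f = factor
        self._shape = None

    def forward(self, x, train: bool = False):
        b, c, d, h, w = x.shape
        f = self.f
        if d % f or h % f or w % f:
            raise ConfigurationError(
                f"spatial dims {(d, h, w)} not divisible by pool factor {f}")
        self._shape = x.shape
        return x.reshape(b, c, d // f, f, h // f, f, w // f, f).mean(axis=(3, 5, 7))

    def backward(self, dout):
        b, c, d, h, w = self._shape
        f = self.f
        dx = np.repeat(np.repeat(np.repeat(dout, f, axis=2), f, axis=3), f, axis=4)
        return dx / np.float32(f ** 3)

    def params(self):
        return []


class GlobalAvgPool3d:
    def __init__(self):
        self._shape = None

    def forward(self, x, train: bool = False):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout):
        b, c, d, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None, None],
                               self._shape) / np.float32(d * h * w)

    def params(self):
        return []


class Linear:
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((out_features, in_features))
                  * np.sqrt(2.0 / in_features)).astype(np.float32)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x, train: bool = False):
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout):
        self.dW[...] = dout.T @ self._x
        self.db[...] = dout.sum(axis=0)
        dx = dout @ self.W
        self._x = None
        return dx

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and gradient w.r.t. logits; labels are 0-based ints."""
    p = softmax(logits)
    n = len(labels)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / np.float32(n)


class Adam:
    """Adam with fixed step size."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
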