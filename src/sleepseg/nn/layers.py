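"""Minimal 1D neural-network layers with explicit forward/backward passes.

Everything operates on a single unbatched ``[channels x time]`` float array
(the pipeline trains with batch size 1: one full sleep record per update).
Each layer caches what its backward pass needs during ``forward`` and
exposes its learnable parameters and their gradients as parallel lists, so
the optimizer can update them in place.  ``state()``/``load_state()``
additionally cover non-learnable buffers (batch-norm running statistics)
for checkpointing.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class; stateless layers only implement forward/backward."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def state(self) -> list[np.ndarray]:
        return self.params()

    def load_state(self, arrays: list[np.ndarray]) -> None:
        for dst, src in zip(self.state(), arrays):
            dst[...] = src

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padded 1D convolution, stride 1, odd kernel.

    Implemented as im2col + matmul: the padded input is unfolded into a
    ``[in_channels * kernel, time]`` matrix so forward and backward are
    single BLAS calls.  He-normal initialization (fan-in = in * kernel).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32):
        if kernel < 1 or kernel % 2 == 0:
            raise ValueError("kernel must be odd and positive")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        std = np.sqrt(2.0 / (in_channels * kernel))
        self.W = rng.normal(0.0, std, (out_channels, in_channels * kernel)).astype(dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training):
        k, p = self.kernel, self.kernel // 2
        c, n = x.shape
        xp = np.pad(x, ((0, 0), (p, p))) if p else x
        # (c, n, k) windows -> (c * k, n) column matrix
        cols = sliding_window_view(xp, k, axis=1)
        colmat = cols.transpose(0, 2, 1).reshape(c * k, n)
        self._colmat = colmat if training else None
        self._n = n
        return self.W @ colmat + self.b[:, None]

    def backward(self, dy):
        k, p = self.kernel, self.kernel // 2
        n = self._n
        self.dW[...] = dy @ self._colmat.T
        self.db[...] = dy.sum(axis=1)
        dcol = (self.W.T @ dy).reshape(self.in_channels, k, n)
        dxp = np.zeros((self.in_channels, n + 2 * p), dtype=dy.dtype)
        for j in range(k):
            dxp[:, j : j + n] += dcol[:, j, :]
        return dxp[:, p : p + n] if p else dxp


class BatchNorm1d(Layer):
    """Per-channel batch normalization over the time axis.

    With batch size 1 and full-length records the per-record time axis gives
    a well-estimated batch statistic.  Running means/variances (exponential
    moving average, update weight ``momentum``) are used in inference mode,
    making prediction deterministic.
    """

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5, dtype=np.float32):
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def state(self):
        return [self.gamma, self.beta, self.running_mean, self.running_var]

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=1)
            var = x.var(axis=1)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None]) * invstd[:, None]
        if training:
            self._xhat = xhat
            self._invstd = invstd.astype(x.dtype)
        return self.gamma[:, None] * xhat + self.beta[:, None]

    def backward(self, dy):
        xhat, invstd = self._xhat, self._invstd
        n = dy.shape[1]
        self.dgamma[...] = (dy * xhat).sum(axis=1)
        self.dbeta[...] = dy.sum(axis=1)
        dxhat = dy * self.gamma[:, None]
        dx = (
            dxhat
            - dxhat.mean(axis=1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=1, keepdims=True)
        ) * invstd[:, None]
        return dx


class ReLU(Layer):
    def forward(self, x, training):
        mask = x > 0
        self._mask = mask if training else None
        return np.where(mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class MaxPool1d(Layer):
    """Non-overlapping max pooling; time length must be divisible."""

    def __init__(self, size: int):
        self.size = size

    def forward(self, x, training):
        c, n = x.shape
        if n % self.size:
            raise ValueError(f"length {n} not divisible by pool {self.size}")
        xr = x.reshape(c, n // self.size, self.size)
        idx = xr.argmax(axis=2)
        if training:
            self._idx = idx
            self._shape = x.shape
        return np.take_along_axis(xr, idx[:, :, None], axis=2)[:, :, 0]

    def backward(self, dy):
        c, n = self._shape
        dxr = np.zeros((c, n // self.size, self.size), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[:, :, None], dy[:, :, None], axis=2)
        return dxr.reshape(c, n)


class AvgPool1d(Layer):
    def __init__(self, size: int):
        self.size = size

    def forward(self, x, training):
        c, n = x.shape
        if n % self.size:
            raise ValueError(f"length {n} not divisible by pool {self.size}")
        self._shape = x.shape
        return x.reshape(c, n // self.size, self.size).mean(axis=2)

    def backward(self, dy):
        c, n = self._shape
        return np.repeat(dy / self.size, self.size, axis=1)


class Upsample1d(Layer):
    """Parameter-free nearest-neighbor (repetition) upscaling."""

    def __init__(self, factor: int):
        self.factor = factor

    def forward(self, x, training):
        return np.repeat(x, self.factor, axis=1)

    def backward(self, dy):
        c, n = dy.shape
        return dy.reshape(c, n // self.factor, self.factor).sum(axis=2)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
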