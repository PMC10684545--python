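"""A small, deterministic NumPy engine for convolutional encoder-decoders.

Implements exactly the layers the reduced U-Net needs — 2-D convolution
(im2col + BLAS matmul), ReLU, 2x2 max pooling, nearest-neighbor
upsampling, channel concatenation, sigmoid — with hand-written
backpropagation and an Adam optimizer.  Everything is float32 and every
source of randomness is an explicit ``numpy.random.Generator``, so runs
are bit-reproducible on one machine.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Conv2d", "ReLU", "MaxPool2", "UpsampleNearest2",
           "Sigmoid", "Adam", "mse_loss"]

DTYPE = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Conv2d:
    """2-D convolution, stride 1, 'same' output size.

    For even kernels the extra padding goes on the bottom/right, so a
    2x2 kernel after nearest upsampling reproduces the classic
    up-convolution parameter count and geometry.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, init_scale: float | None = None):
        fan_in = in_ch * kernel * kernel
        scale = init_scale if init_scale is not None else np.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, scale, size=(fan_in, out_ch))
        self.weight = Param(w)
        self.bias = Param(np.zeros(out_ch))
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        lo = (kernel - 1) // 2
        self._pad = (lo, kernel - 1 - lo)
        self._cache = None

    def parameters(self):
        return [self.weight, self.bias]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.kernel
        pl, pr = self._pad
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr), (pl, pr)))
        cols = np.empty((n, c, k * k, h, w), dtype=DTYPE)
        for ky in range(k):
            for kx in range(k):
                cols[:, :, ky * k + kx] = xp[:, :, ky:ky + h, kx:kx + w]
        # (n, h*w, c*k*k)
        return cols.reshape(n, c * k * k, h * w).transpose(0, 2, 1).copy()

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x)
        y = cols @ self.weight.value + self.bias.value
        self._cache = (cols, x.shape)
        return y.transpose(0, 2, 1).reshape(n, self.out_ch, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w) = self._cache
        k = self.kernel
        dym = dy.reshape(n, self.out_ch, h * w).transpose(0, 2, 1)
        self.weight.grad += np.tensordot(cols, dym, axes=([0, 1], [0, 1]))
        self.bias.grad += dym.sum(axis=(0, 1))
        dcols = dym @ self.weight.value.T  # (n, h*w, c*k*k)
        dcols = dcols.transpose(0, 2, 1).reshape(n, c, k * k, h, w)
        pl, pr = self._pad
        dxp = np.zeros((n, c, h + k - 1, w + k - 1), dtype=DTYPE)
        for ky in range(k):
            for kx in range(k):
                dxp[:, :, ky:ky + h, kx:kx + w] += dcols[:, :, ky * k + kx]
        self._cache = None
        return dxp[:, :, pl:pl + h, pl:pl + w]


class ReLU:
    def __init__(self):
        self._mask = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(DTYPE, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0).astype(DTYPE, copy=False)


class MaxPool2:
    """2x2 max pooling, stride 2."""

    def __init__(self):
        self._cache = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("max pooling requires even spatial size")
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        blocks = blocks.reshape(n, c, h // 2, w // 2, 4)
        idx = blocks.argmax(axis=-1)
        self._cache = (idx, (n, c, h, w))
        return np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        dblocks = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(dblocks, idx[..., None], dy[..., None], axis=-1)
        dblocks = dblocks.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dblocks.reshape(n, c, h, w)


class UpsampleNearest2:
    """Nearest-neighbor 2x upsampling."""

    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sigmoid:
    def __init__(self):
        self._y = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        # numerically stable logistic
        y = np.empty_like(x)
        pos = x >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        y[~pos] = ex / (1.0 + ex)
        self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error and its gradient w.r.t. the prediction."""
    diff = pred - target
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    grad = (2.0 / diff.size) * diff
    return loss, grad.astype(DTYPE, copy=False)


class Adam:
    """Adaptive-moment optimizer (Kingma & Ba defaults)."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self._t += 1
        b1t = 1.0 - self.beta1 ** self._t
        b2t = 1.0 - self.beta2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
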