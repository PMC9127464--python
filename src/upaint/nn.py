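"""Minimal NumPy convolutional-network engine with explicit backpropagation.

Implements exactly the layer set the reconstruction U-Net needs — 2-D
convolution ("same" zero padding), 2x2 transposed convolution, 2x2 max
pooling, ReLU, channel concatenation — plus Adam and plain SGD optimizers.

All activations are float32 in channel-major ``(C, B, H, W)`` layout: with
the channel axis leading, the batch and spatial axes flatten into the
column dimension of a single BLAS matrix product per convolution
(``weight (Cout, C*k*k) @ patches (C*k*k, B*H*W)``), so neither the forward
nor the backward pass needs per-sample looping.  Gradients are derived
layer-by-layer in closed form; the data gradient of a convolution is
evaluated as a full correlation with the 180deg-rotated kernel, again one
im2col plus one GEMM.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv2d",
    "ConvTranspose2d",
    "MaxPool2",
    "ReLU",
    "Adam",
    "SGD",
    "mse_loss",
]


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


def _im2col(xp: np.ndarray, k: int) -> np.ndarray:
    """Patch matrix (C*k*k, B*Ho*Wo) from a pre-padded (C, B, Hp, Wp) input."""
    C, B = xp.shape[0], xp.shape[1]
    if k == 1:
        return np.ascontiguousarray(xp).reshape(C, -1)
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # C,B,Ho,Wo,k,k
    win = win.transpose(0, 4, 5, 1, 2, 3)
    return np.ascontiguousarray(win).reshape(C * k * k, -1)


class Conv2d:
    """k x k convolution, stride 1, symmetric zero padding.

    Weights are stored flattened as (out_channels, in_channels * k * k) so the
    forward pass is a single matmul against the im2col patch matrix.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 padding: int | None = None, rng: np.random.Generator | None = None):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        self.pad = (kernel_size // 2) if padding is None else padding
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        # He initialization: suited to the ReLU nonlinearity that follows
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, fan_in))
        self.weight = Param(w)
        self.bias = Param(np.zeros(out_channels))
        #: set False on a network's first layer, whose input gradient is unused
        self.compute_dx = True
        self._cols: np.ndarray | None = None
        self._x_shape: tuple | None = None

    @property
    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        C, B, H, W = x.shape
        k, p = self.k, self.pad
        Ho, Wo = H - k + 2 * p + 1, W - k + 2 * p + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = _im2col(xp, k)
        self._cols = cols
        self._x_shape = x.shape
        y = self.weight.value @ cols
        y += self.bias.value[:, None]
        return y.reshape(self.out_channels, B, Ho, Wo)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        C, B, H, W = self._x_shape
        k, p = self.k, self.pad
        dyf = dy.reshape(self.out_channels, -1)
        self.weight.grad += dyf @ self._cols.T
        self.bias.grad += dyf.sum(axis=1)
        self._cols = None
        if not self.compute_dx:
            return np.zeros((C, B, H, W), dtype=np.float32)
        q = k - 1 - p
        dyp = np.pad(dy, ((0, 0), (0, 0), (q, q), (q, q))) if q else dy
        dycols = _im2col(dyp, k)
        wrot = (self.weight.value
                .reshape(self.out_channels, C, k * k)[:, :, ::-1]
                .transpose(1, 0, 2)
                .reshape(C, self.out_channels * k * k))
        dx = np.ascontiguousarray(wrot) @ dycols
        return dx.reshape(C, B, H, W)


class ConvTranspose2d:
    """2x2 transposed convolution with stride 2 (resolution doubling)."""

    _OFFSETS = ((0, 0), (0, 1), (1, 0), (1, 1))

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None):
        self.in_channels = in_channels
        self.out_channels = out_channels
        rng = rng or np.random.default_rng()
        fan_in = in_channels  # each output pixel receives one kernel tap
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(4, in_channels, out_channels))
        self.weight = Param(w)
        self.bias = Param(np.zeros(out_channels))
        self._x: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        C, B, H, W = x.shape
        self._x = x
        xf = x.reshape(C, -1)
        y = np.empty((self.out_channels, B, 2 * H, 2 * W), dtype=np.float32)
        for idx, (di, dj) in enumerate(self._OFFSETS):
            block = self.weight.value[idx].T @ xf
            y[:, :, di::2, dj::2] = block.reshape(self.out_channels, B, H, W)
        y += self.bias.value[:, None, None, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        C, B, H, W = x.shape
        xf = x.reshape(C, -1)
        dxf = np.zeros_like(xf)
        for idx, (di, dj) in enumerate(self._OFFSETS):
            dyf = np.ascontiguousarray(dy[:, :, di::2, dj::2]).reshape(self.out_channels, -1)
            self.weight.grad[idx] += xf @ dyf.T
            dxf += self.weight.value[idx] @ dyf
        self.bias.grad += dy.sum(axis=(1, 2, 3))
        self._x = None
        return dxf.reshape(C, B, H, W)


class MaxPool2:
    """2x2 max pooling, stride 2."""

    def __init__(self):
        self._argmax: np.ndarray | None = None
        self._x_shape: tuple | None = None

    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        C, B, H, W = x.shape
        v = x.reshape(C, B, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        v = np.ascontiguousarray(v).reshape(C, B, H // 2, W // 2, 4)
        self._argmax = v.argmax(axis=-1)
        self._x_shape = x.shape
        return v.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        C, B, H, W = self._x_shape
        dv = np.zeros((C, B, H // 2, W // 2, 4), dtype=np.float32)
        np.put_along_axis(dv, self._argmax[..., None], dy[..., None], axis=-1)
        dv = dv.reshape(C, B, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._argmax = None
        return np.ascontiguousarray(dv).reshape(C, B, H, W)


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        # operates in place: the caller's buffer is always a fresh conv output
        self._mask = x > 0
        return np.maximum(x, np.float32(0.0), out=x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy *= self._mask
        self._mask = None
        return dy


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. ``pred``."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    grad = (2.0 / diff.size) * diff
    return loss, grad.astype(np.float32, copy=False)


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class SGD:
    """Plain stochastic gradient descent."""

    def __init__(self, params: list[Param], lr: float = 1e-2):
        self.params = params
        self.lr = lr

    def step(self) -> None:
        for p in self.params:
            p.value -= self.lr * p.grad

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
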