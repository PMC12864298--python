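"""Minimal NCHW layer zoo with manual backpropagation.

Each layer instance is used at exactly one site in a network, caches what its
backward pass needs during forward, and accumulates parameter gradients into
``Param.grad`` (zeroed by the optimizer step or ``Model.zero_grad``).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Conv2d:
    """2-D convolution, stride 1, 'same' padding for odd kernel sizes."""

    def __init__(self, c_in: int, c_out: int, ksize: int = 3, rng=None):
        if ksize % 2 == 0:
            raise ValueError("only odd kernel sizes supported")
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out, self.k = c_in, c_out, ksize
        self.pad = ksize // 2
        fan_in = c_in * ksize * ksize
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, fan_in)))
        self.b = Param(np.zeros(c_out))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        k = self.k
        if k == 1:
            cols = x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
            win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (n, c, h, w, k, k)
            cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        y = cols @ self.W.value.T + self.b.value
        self._cache = (cols, x.shape)
        return y.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, c, h, w = xshape
        k = self.k
        g = gy.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.W.grad += g.T @ cols
        self.b.grad += g.sum(axis=0)
        dcols = g @ self.W.value
        if k == 1:
            return dcols.reshape(n, h, w, c).transpose(0, 3, 1, 2)
        d = dcols.reshape(n, h, w, c, k, k)
        gpad = np.zeros((n, c, h + 2 * self.pad, w + 2 * self.pad))
        for ki in range(k):
            for kj in range(k):
                gpad[:, :, ki : ki + h, kj : kj + w] += d[:, :, :, :, ki, kj].transpose(
                    0, 3, 1, 2
                )
        return gpad[:, :, self.pad : self.pad + h, self.pad : self.pad + w]


class BatchNorm2d:
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, training)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv_std, training = self._cache
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        gscale = self.gamma.value[None, :, None, None] * inv_std[None, :, None, None]
        if not training:
            return gy * gscale
        n, _, h, w = gy.shape
        m = n * h * w
        dxhat = gy * self.gamma.value[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (inv_std[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2; dimensions must be even."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"pooling needs even dimensions, got {h}x{w}")
        v = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        idx = v.argmax(axis=-1)
        self._cache = (idx, x.shape)
        return np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        idx, xshape = self._cache
        n, c, h, w = xshape
        g4 = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(g4, idx[..., None], gy[..., None], axis=-1)
        return g4.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h, w
        )


class UpsampleNearest2:
    """Nearest-neighbour 2x upsampling; backward sums each 2x2 block."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = gy.shape
        return gy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class ConvBlock:
    """(3x3 conv + batch norm + ReLU) x 2 — the standard encoder/decoder unit."""

    def __init__(self, c_in: int, c_out: int, rng=None):
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        self.bn1 = BatchNorm2d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, rng)
        self.bn2 = BatchNorm2d(c_out)
        self.relu2 = ReLU()

    def params(self):
        return (
            self.conv1.params()
            + self.bn1.params()
            + self.conv2.params()
            + self.bn2.params()
        )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, training), training))
        return self.relu2.forward(self.bn2.forward(self.conv2.forward(x, training), training))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gy = self.conv2.backward(self.bn2.backward(self.relu2.backward(gy)))
        return self.conv1.backward(self.bn1.backward(self.relu1.backward(gy)))
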