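"""Minimal 1-D convolutional network engine in NumPy.

Implements exactly the layer set the ROI detector needs — temporal 1-D
convolution, batch normalization, ReLU, residual blocks with projection
shortcuts, global average pooling, a dense head and Adam — with explicit
forward and backward passes. Tensors are time-major per sample:
``(batch, length, channels)``.

Conventions:

* Convolutions use "same"-style zero padding: output length is
  ``ceil(L / stride)``; pad total = max((out-1)*stride + k - L, 0),
  split left = pad // 2.
* Batch norm reduces over batch and time for conv features, batch only
  for dense features; running statistics (momentum 0.9) are used at
  inference.
* All parameter initialisation is driven by a caller-supplied
  ``numpy.random.Generator`` — same generator, same weights.

Gradients of every layer are verified against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Conv1d", "BatchNorm", "ReLU", "Dense", "GlobalAvgPool",
    "ResidualBlock", "Adam", "conv_out_len", "sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def conv_out_len(l: int, stride: int) -> int:
    return -(-l // stride)  # ceil


class Param:
    """A tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []


class Conv1d(Layer):
    """1-D convolution along time, kernel ``k``, stride ``s``, zero-padded."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        scale = np.sqrt(2.0 / (k * c_in))  # He init for ReLU stacks
        self.w = Param(rng.normal(0.0, scale, size=(k * c_in, c_out)))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.w, self.b]

    def _geometry(self, l: int):
        out = conv_out_len(l, self.stride)
        pad = max((out - 1) * self.stride + self.k - l, 0)
        return out, pad // 2, pad - pad // 2

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, l, c = x.shape
        out, pl, pr = self._geometry(l)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        # im2col: (B, out, k, C) gathered at stride steps
        starts = np.arange(out) * self.stride
        idx = starts[:, None] + np.arange(self.k)[None, :]
        col = xp[:, idx, :]  # (B, out, k, C)
        self._cache = (col, l, pl, xp.shape[1])
        y = col.reshape(b, out, self.k * c) @ self.w.value + self.b.value
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        col, l, pl, lp = self._cache
        b, out, k, c = col.shape
        gf = g.reshape(b * out, self.c_out)
        self.w.grad += col.reshape(b * out, k * c).T @ gf
        self.b.grad += gf.sum(axis=0)
        dcol = (g @ self.w.value.T).reshape(b, out, k, c)
        dxp = np.zeros((b, lp, c))
        starts = np.arange(out) * self.stride
        for j in range(k):
            # for fixed j the target positions are distinct -> plain add
            dxp[:, starts + j, :] += dcol[:, :, j, :]
        return dxp[:, pl:pl + l, :]


class BatchNorm(Layer):
    """Batch normalization over (batch, time) for 3-D input, batch for 2-D."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, axes, train, x.shape)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv, axes, train, shape = self._cache
        self.gamma.grad += (g * xhat).sum(axis=axes)
        self.beta.grad += g.sum(axis=axes)
        gxhat = g * self.gamma.value
        if not train:
            return gxhat * inv
        n = np.prod([shape[a] for a in axes])
        return (inv / n) * (
            n * gxhat - gxhat.sum(axis=axes) - xhat * (gxhat * xhat).sum(axis=axes)
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class GlobalAvgPool(Layer):
    """Mean over the time axis: (B, L, C) -> (B, C)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._l = x.shape[1]
        return x.mean(axis=1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.repeat(g[:, None, :], self._l, axis=1) / self._l


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / c_in)
        self.w = Param(rng.normal(0.0, scale, size=(c_in, c_out)))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.w.value.T


class ResidualBlock(Layer):
    """conv(s=2) -> BN -> ReLU -> conv(s=1) -> BN, plus a projection
    shortcut (1x1 conv, stride 2, BN), summed and passed through ReLU.

    The stride-2 first convolution stands in for a pooling layer; the
    shortcut keeps optimisation well-conditioned as depth grows.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 2):
        self.conv1 = Conv1d(c_in, c_out, k, stride, rng)
        self.bn1 = BatchNorm(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv1d(c_out, c_out, k, 1, rng)
        self.bn2 = BatchNorm(c_out)
        self.proj = Conv1d(c_in, c_out, 1, stride, rng)
        self.bn_proj = BatchNorm(c_out)
        self.relu_out = ReLU()

    def params(self):
        ps = []
        for layer in (self.conv1, self.bn1, self.conv2, self.bn2, self.proj, self.bn_proj):
            ps += layer.params()
        return ps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        y = self.bn2.forward(self.conv2.forward(y, train), train)
        s = self.bn_proj.forward(self.proj.forward(x, train), train)
        return self.relu_out.forward(y + s, train)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(g)
        gs = self.proj.backward(self.bn_proj.backward(g))
        gy = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(
                self.conv2.backward(self.bn2.backward(g))))
        )
        return gy + gs


class Adam:
    """Adam optimiser over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
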