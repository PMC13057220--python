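"""Minimal NumPy neural-network layers for CPU-scale phantom experiments.

Implements exactly what the age regressor needs: N-dimensional convolution
(stride 1, "same" padding), instance normalization, ReLU, 2x average
pooling, global average pooling and a dense head, each with a hand-written
backward pass, plus an Adam optimizer.  All layers cache their forward
inputs so a backward sweep can recover gradients with respect to any
intermediate activation (used for Grad-CAM).

Arrays are channel-first: ``(batch, channels, *spatial)`` with 2 or 3
spatial axes.  float32 throughout.
"""

from __future__ import annotations

import itertools

import numpy as np

DTYPE = np.float32


class Layer:
    """Base class: stateless unless it owns parameters."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


class ConvND(Layer):
    """Cross-correlation with odd kernel, stride 1, zero "same" padding.

    Forward lowers the input to a column matrix (im2col via
    ``sliding_window_view``) and multiplies by the flattened kernel; backward
    scatters the column gradient back with one slice-add per kernel offset,
    so no index arithmetic beyond array slicing is needed.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, ndim: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.kernel, self.ndim = c_in, c_out, kernel, ndim
        fan_in = c_in * kernel**ndim
        # He initialization: ReLU follows every conv in the blocks
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        self.weight = w.astype(DTYPE)
        self.bias = np.zeros(c_out, dtype=DTYPE)
        self.params = [self.weight, self.bias]
        self.grads = [np.zeros_like(self.weight), np.zeros_like(self.bias)]
        self._cols: np.ndarray | None = None
        self._spatial: tuple[int, ...] = ()

    def forward(self, x: np.ndarray) -> np.ndarray:
        nd, k, p = self.ndim, self.kernel, self.kernel // 2
        b = x.shape[0]
        spatial = x.shape[2:]
        pad = [(0, 0), (0, 0)] + [(p, p)] * nd
        xp = np.pad(x, pad)
        win = np.lib.stride_tricks.sliding_window_view(xp, (k,) * nd, axis=tuple(range(2, 2 + nd)))
        # win: (b, c_in, *spatial, *k) -> cols: (b * prod(spatial), c_in * k**nd)
        win = np.moveaxis(win, 1, 1 + nd)  # (b, *spatial, c_in, *k)
        cols = np.ascontiguousarray(win).reshape(b * int(np.prod(spatial)), -1)
        y = cols @ self.weight.T + self.bias
        self._cols, self._spatial = cols, spatial
        y = y.reshape(b, *spatial, self.c_out)
        return np.moveaxis(y, -1, 1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        nd, k, p = self.ndim, self.kernel, self.kernel // 2
        b = grad.shape[0]
        spatial = self._spatial
        gf = np.moveaxis(grad, 1, -1).reshape(-1, self.c_out)
        self.grads[0] += (gf.T @ self._cols).astype(DTYPE)
        self.grads[1] += gf.sum(axis=0, dtype=np.float64).astype(DTYPE)
        dcols = (gf @ self.weight).reshape(b, *spatial, self.c_in, *(k,) * nd)
        dcols = np.moveaxis(dcols, 1 + nd, 1)  # (b, c_in, *spatial, *k)
        padded = np.zeros((b, self.c_in) + tuple(s + 2 * p for s in spatial), dtype=DTYPE)
        for off in itertools.product(range(k), repeat=nd):
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + s) for o, s in zip(off, spatial)
            )
            padded[sl] += dcols[(Ellipsis, *off)]
        core = (slice(None), slice(None)) + tuple(slice(p, p + s) for s in spatial)
        self._cols = None
        return padded[core]


class InstanceNorm(Layer):
    """Per-sample, per-channel normalization over spatial axes with affine."""

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self._xhat: np.ndarray | None = None
        self._istd: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = tuple(range(2, x.ndim))
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * istd
        self._xhat, self._istd = xhat, istd
        shape = (1, -1) + (1,) * (x.ndim - 2)
        return self.gamma.reshape(shape) * xhat + self.beta.reshape(shape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes = tuple(range(2, grad.ndim))
        xhat, istd = self._xhat, self._istd
        sum_axes = (0,) + axes
        self.grads[0] += (grad * xhat).sum(axis=sum_axes, dtype=np.float64).astype(DTYPE)
        self.grads[1] += grad.sum(axis=sum_axes, dtype=np.float64).astype(DTYPE)
        shape = (1, -1) + (1,) * (grad.ndim - 2)
        dxhat = grad * self.gamma.reshape(shape)
        m1 = dxhat.mean(axis=axes, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
        self._xhat = self._istd = None
        return istd * (dxhat - m1 - xhat * m2)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._mask
        self._mask = None
        return out


class AvgPool2(Layer):
    """Non-overlapping 2x downsampling; spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        nd = x.ndim - 2
        if any(s % 2 for s in x.shape[2:]):
            raise ValueError(f"spatial shape {x.shape[2:]} not divisible by 2")
        shape = x.shape[:2]
        for s in x.shape[2:]:
            shape = shape + (s // 2, 2)
        xr = x.reshape(shape)
        axes = tuple(3 + 2 * i for i in range(nd))
        self._in_shape = x.shape
        return xr.mean(axis=axes)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        nd = grad.ndim - 2
        g = grad / (2**nd)
        for ax in range(2, 2 + nd):
            g = np.repeat(g, 2, axis=ax)
        return g.astype(DTYPE, copy=False)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        shape = self._in_shape
        m = int(np.prod(shape[2:]))
        g = (grad / m).reshape(shape[:2] + (1,) * (len(shape) - 2))
        return np.broadcast_to(g, shape).astype(DTYPE, copy=False)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = rng.normal(0.0, np.sqrt(1.0 / n_in), size=(n_out, n_in)).astype(DTYPE)
        self.bias = np.zeros(n_out, dtype=DTYPE)
        self.params = [self.weight, self.bias]
        self.grads = [np.zeros_like(self.weight), np.zeros_like(self.bias)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.T + self.bias

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0] += (grad.T @ self._x).astype(DTYPE)
        self.grads[1] += grad.sum(axis=0, dtype=np.float64).astype(DTYPE)
        out = grad @ self.weight
        self._x = None
        return out


class ResidualBlock(Layer):
    """conv3 -> instance norm, added to a 1x1-conv projection, ReLU, 2x pool.

    The post-ReLU, pre-pool activation and its upstream gradient are kept on
    ``activation`` / ``activation_grad`` after forward/backward so attention
    maps can be formed from them.
    """

    def __init__(self, c_in: int, c_out: int, ndim: int, rng: np.random.Generator):
        super().__init__()
        self.conv = ConvND(c_in, c_out, 3, ndim, rng)
        self.norm = InstanceNorm(c_out)
        self.proj = ConvND(c_in, c_out, 1, ndim, rng)
        self.relu = ReLU()
        self.pool = AvgPool2()
        self._subs = [self.conv, self.norm, self.proj]
        self.params = [p for l in self._subs for p in l.params]
        self.grads = [g for l in self._subs for g in l.grads]
        self.activation: np.ndarray | None = None
        self.activation_grad: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.norm.forward(self.conv.forward(x)) + self.proj.forward(x)
        a = self.relu.forward(h)
        self.activation = a
        return self.pool.forward(a)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        da = self.pool.backward(grad)
        self.activation_grad = da
        dh = self.relu.backward(da)
        return self.conv.backward(self.norm.backward(dh)) + self.proj.backward(dh)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers
        self.params = [p for l in layers for p in l.params]
        self.grads = [g for l in layers for g in l.grads]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad

    def zero_grad(self) -> None:
        for l in self.layers:
            l.zero_grad()


class Adam:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central-difference gradient of scalar f at x (test utility)."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
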