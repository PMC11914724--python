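"""Minimal NumPy layers with explicit backprop.

Just enough machinery for the desk-scale survival networks: dense and
strided 1D/2D convolutions (im2col), ReLU, residual blocks, global average
pooling and Adam. Every layer caches what its backward pass needs and
``backward`` always returns the gradient with respect to its input, which
is what makes vanilla-gradient saliency maps free.

Array layout is channels-last: (N, L, C) for 1D, (N, H, W, C) for 2D.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / cin)
        self.w = Param(rng.normal(0.0, std, size=(cin, cout)))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return dy * self._mask


class BatchNorm(Layer):
    """Per-channel (last-axis) batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.run_mean = np.zeros(channels)
        self.run_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._axes = axes
        self._train = train
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dy):
        axes = self._axes
        self.gamma.grad += (dy * self._xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.value
        if not self._train:
            return dxhat / self._std
        m = np.prod([self._xhat.shape[a] for a in axes])
        return (dxhat - dxhat.mean(axis=axes)
                - self._xhat * (dxhat * self._xhat).mean(axis=axes)) / self._std


class Conv1D(Layer):
    """Strided 1D convolution, zero-padded to keep L_out = ceil(L/stride)."""

    def __init__(self, cin: int, cout: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        self.kernel, self.stride, self.cin, self.cout = kernel, stride, cin, cout
        std = np.sqrt(2.0 / (cin * kernel))
        # weight rows follow the im2col layout: channel-major, tap-minor
        self.w = Param(rng.normal(0.0, std, size=(cin * kernel, cout)))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.w, self.b]

    def _pad(self, length: int) -> tuple[int, int]:
        l_out = int(np.ceil(length / self.stride))
        total = max(0, (l_out - 1) * self.stride + self.kernel - length)
        return total // 2, total - total // 2

    def forward(self, x, train=False):
        n, length, _ = x.shape
        p0, p1 = self._pad(length)
        xp = np.pad(x, ((0, 0), (p0, p1), (0, 0)))
        win = sliding_window_view(xp, self.kernel, axis=1)  # (N, L', C, k)
        win = win[:, :: self.stride]
        self._cols = win.reshape(n, win.shape[1], -1)  # (N, L_out, C*k)
        y = self._cols @ self.w.value
        self._shape = (n, length, p0, p1, win.shape[1])
        return y + self.b.value

    def backward(self, dy):
        n, length, p0, p1, l_out = self._shape
        self.b.grad += dy.sum(axis=(0, 1))
        self.w.grad += np.einsum("nlf,nlo->fo", self._cols, dy)
        dcols = dy @ self.w.value.T  # (N, L_out, C*k)
        dcols = dcols.reshape(n, l_out, self.cin, self.kernel)
        dxp = np.zeros((n, length + p0 + p1, self.cin))
        pos = self.stride * np.arange(l_out)
        for t in range(self.kernel):
            dxp[:, pos + t, :] += dcols[:, :, :, t]
        return dxp[:, p0: p0 + length, :]


class Conv2D(Layer):
    """Strided 2D convolution with symmetric zero padding (same-style)."""

    def __init__(self, cin: int, cout: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        self.kernel, self.stride, self.cin, self.cout = kernel, stride, cin, cout
        std = np.sqrt(2.0 / (cin * kernel * kernel))
        self.w = Param(rng.normal(0.0, std, size=(kernel * kernel * cin, cout)))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.w, self.b]

    def _pad(self, size: int) -> tuple[int, int, int]:
        out = int(np.ceil(size / self.stride))
        total = max(0, (out - 1) * self.stride + self.kernel - size)
        return total // 2, total - total // 2, out

    def forward(self, x, train=False):
        n, h, w, _ = x.shape
        ph0, ph1, ho = self._pad(h)
        pw0, pw1, wo = self._pad(w)
        xp = np.pad(x, ((0, 0), (ph0, ph1), (pw0, pw1), (0, 0)))
        win = sliding_window_view(xp, (self.kernel, self.kernel), axis=(1, 2))
        win = win[:, :: self.stride, :: self.stride]  # (N, Ho, Wo, C, kh, kw)
        self._cols = win.reshape(n, ho, wo, -1)
        y = self._cols @ self.w.value
        self._shape = (n, h, w, ph0, ph1, pw0, pw1, ho, wo)
        return y + self.b.value

    def backward(self, dy):
        n, h, w, ph0, ph1, pw0, pw1, ho, wo = self._shape
        self.b.grad += dy.sum(axis=(0, 1, 2))
        self.w.grad += np.einsum("nhwf,nhwo->fo", self._cols, dy)
        dcols = (dy @ self.w.value.T).reshape(n, ho, wo, self.cin, self.kernel, self.kernel)
        dxp = np.zeros((n, h + ph0 + ph1, w + pw0 + pw1, self.cin))
        ri = self.stride * np.arange(ho)
        ci = self.stride * np.arange(wo)
        for ti in range(self.kernel):
            for tj in range(self.kernel):
                dxp[:, (ri + ti)[:, None], (ci + tj)[None, :], :] += dcols[:, :, :, :, ti, tj]
        return dxp[:, ph0: ph0 + h, pw0: pw0 + w, :]


class GlobalAvgPool(Layer):
    """Mean over all spatial axes: (N, ..., C) -> (N, C)."""

    def forward(self, x, train=False):
        self._shape = x.shape
        axes = tuple(range(1, x.ndim - 1))
        return x.mean(axis=axes)

    def backward(self, dy):
        shape = self._shape
        n_spatial = int(np.prod(shape[1:-1]))
        expand = (shape[0],) + (1,) * (len(shape) - 2) + (shape[-1],)
        return np.broadcast_to(dy.reshape(expand), shape) / n_spatial


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class ResidualBlock1D(Layer):
    """conv-relu-conv with an (optionally projected) shortcut, then ReLU."""

    def __init__(self, cin: int, cout: int, kernel: int, stride: int,
                 rng: np.random.Generator, batch_norm: bool = True):
        inner: list[Layer] = [Conv1D(cin, cout, kernel, stride, rng)]
        if batch_norm:
            inner.append(BatchNorm(cout))
        inner.append(ReLU())
        inner.append(Conv1D(cout, cout, kernel, 1, rng))
        if batch_norm:
            inner.append(BatchNorm(cout))
        self.branch = Sequential(inner)
        self.project = None
        if cin != cout or stride != 1:
            self.project = Conv1D(cin, cout, 1, stride, rng)
        self.relu = ReLU()

    def params(self):
        ps = self.branch.params()
        if self.project is not None:
            ps = ps + self.project.params()
        return ps

    def forward(self, x, train=False):
        main = self.branch.forward(x, train)
        short = x if self.project is None else self.project.forward(x, train)
        return self.relu.forward(main + short, train)

    def backward(self, dy):
        dy = self.relu.backward(dy)
        dx = self.branch.backward(dy)
        dx_short = dy if self.project is None else self.project.backward(dy)
        return dx + dx_short


class InvertedBottleneck2D(Layer):
    """Expand (1x1) - spatial (3x3, optional stride) - project (1x1).

    A desk-scale take on the mobile inverted bottleneck: the spatial
    convolution is a full convolution rather than depthwise. Residual
    connection when shape is preserved.
    """

    def __init__(self, cin: int, cout: int, stride: int,
                 rng: np.random.Generator, expansion: int = 2):
        mid = expansion * cin
        self.body = Sequential([
            Conv2D(cin, mid, 1, 1, rng),
            BatchNorm(mid),
            ReLU(),
            Conv2D(mid, mid, 3, stride, rng),
            BatchNorm(mid),
            ReLU(),
            Conv2D(mid, cout, 1, 1, rng),
            BatchNorm(cout),
        ])
        self.residual = cin == cout and stride == 1

    def params(self):
        return self.body.params()

    def forward(self, x, train=False):
        y = self.body.forward(x, train)
        if self.residual:
            self._had_residual = True
            return y + x
        self._had_residual = False
        return y

    def backward(self, dy):
        dx = self.body.backward(dy)
        return dx + dy if self._had_residual else dx


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
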