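"""Layers, parameter container and Adam optimiser.

Weight initialisation is Xavier-uniform; convolution and linear kernels are
additionally orthogonalised (QR of the Xavier draw, rescaled to the Xavier
row norm) where the shape permits, so initial filters are orthogonal to each
other.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)


def _xavier_orthogonal(rng: np.random.Generator, n_out: int, n_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    w = rng.uniform(-limit, limit, (n_out, n_in))
    if n_out <= n_in:
        q, _ = np.linalg.qr(w.T)  # (n_in, n_out), orthonormal columns
        scale = limit / np.sqrt(3.0) * np.sqrt(n_in)  # match Xavier row norm
        w = q.T * scale
    return w.astype(DTYPE)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def _im2col(x, k, stride, pad):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (n, c, oh, ow, k, k)
    oh, ow = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(dcols, x_shape, k, stride, pad, oh, ow):
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=DTYPE)
    d6 = dcols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for a in range(k):
        for b in range(k):
            dxp[:, :, a:a + oh * stride:stride, b:b + ow * stride:stride] += d6[..., a, b]
    return dxp[:, :, pad:pad + h, pad:pad + w]


class Conv2d(Layer):
    def __init__(self, c_in, c_out, rng, k=3, stride=1, pad=1):
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        self.W = Param(_xavier_orthogonal(rng, c_out, c_in * k * k))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x_shape = x.shape
        cols, oh, ow = _im2col(x, self.k, self.stride, self.pad)
        self._cols, self._oh, self._ow = cols, oh, ow
        y = cols @ self.W.value.T + self.b.value
        return y.reshape(x.shape[0], oh, ow, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy):
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        self.W.grad += dyf.T @ self._cols
        self.b.grad += dyf.sum(0)
        dcols = dyf @ self.W.value
        return _col2im(dcols, self._x_shape, self.k, self.stride, self.pad,
                       self._oh, self._ow)


class ConvTranspose2d(Layer):
    """Stride-2, kernel-2 transposed convolution (non-overlapping upsampling)."""

    def __init__(self, c_in, c_out, rng):
        self.c_in, self.c_out = c_in, c_out
        w = _xavier_orthogonal(rng, c_out, c_in * 4)
        self.W = Param(w.reshape(c_out, c_in, 2, 2).transpose(1, 0, 2, 3))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        n, _, h, w = x.shape
        t = np.einsum("nihw,ioab->nohwab", x, self.W.value, optimize=True)
        y = t.transpose(0, 1, 2, 4, 3, 5).reshape(n, self.c_out, 2 * h, 2 * w)
        return y + self.b.value[None, :, None, None]

    def backward(self, dy):
        n, _, H, W = dy.shape
        h, w = H // 2, W // 2
        d6 = dy.reshape(n, self.c_out, h, 2, w, 2).transpose(0, 1, 2, 4, 3, 5)
        self.W.grad += np.einsum("nihw,nohwab->ioab", self._x, d6, optimize=True)
        self.b.grad += dy.sum((0, 2, 3))
        return np.einsum("nohwab,ioab->nihw", d6, self.W.value, optimize=True)


class MaxPool2d(Layer):
    def forward(self, x, train):
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = r.max(axis=(3, 5))
        self._mask = r == y[:, :, :, None, :, None]
        self._shape = x.shape
        return y

    def backward(self, dy):
        n, c, h, w = self._shape
        d = self._mask * dy[:, :, :, None, :, None]
        # split ties evenly so gradient mass is conserved
        counts = self._mask.sum(axis=(3, 5), keepdims=True)
        return (d / counts).reshape(n, c, h, w)


class ReLU(Layer):
    def forward(self, x, train):
        self._m = x > 0
        return x * self._m

    def backward(self, dy):
        return dy * self._m


class Softplus(Layer):
    def forward(self, x, train):
        self._x = x
        return np.logaddexp(0, x).astype(DTYPE)

    def backward(self, dy):
        # numerically stable sigmoid
        pos = self._x >= 0
        z = np.exp(-np.abs(self._x))
        sig = np.where(pos, 1.0 / (1.0 + z), z / (1.0 + z))
        return dy * sig


class Dropout(Layer):
    def __init__(self, rng, p=0.5):
        self.p, self._rng = p, rng

    def forward(self, x, train):
        if not train or self.p == 0:
            self._m = None
            return x
        self._m = (self._rng.random(x.shape) >= self.p).astype(DTYPE) / (1 - self.p)
        return x * self._m

    def backward(self, dy):
        return dy if self._m is None else dy * self._m


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in, n_out, rng):
        self.W = Param(_xavier_orthogonal(rng, n_out, n_in))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dy):
        self.W.grad += dy.T @ self._x
        self.b.grad += dy.sum(0)
        return dy @ self.W.value


class _BatchNorm(Layer):
    def __init__(self, n, momentum=0.1, eps=1e-5):
        self.gamma = Param(np.ones(n))
        self.beta = Param(np.zeros(n))
        self.running_mean = np.zeros(n, dtype=DTYPE)
        self.running_var = np.ones(n, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def _norm(self, x, axes, train):
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        return mean, var


class BatchNorm1d(_BatchNorm):
    def forward(self, x, train):
        mean, var = self._norm(x, 0, train)
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._train = train
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dy):
        self.gamma.grad += (dy * self._xhat).sum(0)
        self.beta.grad += dy.sum(0)
        if not self._train:
            return dy * self.gamma.value / self._std
        n = dy.shape[0]
        dxhat = dy * self.gamma.value
        return (dxhat - dxhat.mean(0) - self._xhat * (dxhat * self._xhat).mean(0)) / self._std


class BatchNorm2d(_BatchNorm):
    def forward(self, x, train):
        mean, var = self._norm(x, (0, 2, 3), train)
        m, s = mean[None, :, None, None], np.sqrt(var + self.eps)[None, :, None, None]
        self._std = s
        self._xhat = (x - m) / s
        self._train = train
        return self.gamma.value[None, :, None, None] * self._xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, dy):
        self.gamma.grad += (dy * self._xhat).sum((0, 2, 3))
        self.beta.grad += dy.sum((0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not self._train:
            return dy * g / self._std
        dxhat = dy * g
        mean_d = dxhat.mean((0, 2, 3), keepdims=True)
        mean_dx = (dxhat * self._xhat).mean((0, 2, 3), keepdims=True)
        return (dxhat - mean_d - self._xhat * mean_dx) / self._std


class Adam:
    """Adam with decoupled-from-nothing plain L2 weight decay added to gradients."""

    def __init__(self, params: list[Param], lr=1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-8, weight_decay=0.0):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]
        self._t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self._t += 1
        b1t = 1 - self.beta1 ** self._t
        b2t = 1 - self.beta2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p.value -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
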