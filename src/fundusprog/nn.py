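"""Minimal CPU neural-network stack (NumPy, explicit backprop).

Implements exactly the layers the package's models need: strided
convolutions, transposed convolutions, instance normalization, dropout,
dense layers and the usual activations, plus an Adam optimizer.  Layers
follow a two-method protocol — ``forward(x, train=...)`` caches what the
matching ``backward(dout)`` needs; ``backward`` accumulates parameter
gradients and returns the gradient with respect to the input, which is
what GAN generator updates and input-saliency maps require.

All parameter initialization is driven by an explicit ``rng`` so model
construction is reproducible.  Every layer is verified against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)


class Layer:
    def params(self) -> list:
        return []

    def forward(self, x, train: bool = False):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError


def _he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Layer):
    """2-D convolution (cross-correlation), stride ``s``, symmetric zero pad."""

    def __init__(self, c_in, c_out, kernel=3, stride=1, pad=None, rng=None):
        rng = rng or np.random.default_rng(0)
        self.k, self.s = kernel, stride
        self.p = (kernel - 1) // 2 if pad is None else pad
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * kernel * kernel
        self.W = Param(_he_init(rng, (c_out, c_in, kernel, kernel), fan_in))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def _gather(self, xp, Ho, Wo):
        N, C = xp.shape[:2]
        k, s = self.k, self.s
        cols = np.empty((N, C, k, k, Ho, Wo), dtype=xp.dtype)
        for ki in range(k):
            for kj in range(k):
                cols[:, :, ki, kj] = xp[:, :, ki:ki + s * Ho:s, kj:kj + s * Wo:s]
        return cols

    def forward(self, x, train=False):
        N, C, H, W = x.shape
        k, s, p = self.k, self.s, self.p
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = self._gather(xp, Ho, Wo)
        self._cache = (cols, x.shape)
        cols2 = cols.transpose(0, 4, 5, 1, 2, 3).reshape(N * Ho * Wo, -1)
        Wm = self.W.data.reshape(self.c_out, -1)
        y = cols2 @ Wm.T + self.b.data
        return y.reshape(N, Ho, Wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, xshape = self._cache
        N, C, H, W = xshape
        k, s, p = self.k, self.s, self.p
        _, _, Ho, Wo = dout.shape
        dy2 = dout.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        cols2 = cols.transpose(0, 4, 5, 1, 2, 3).reshape(dy2.shape[0], -1)
        self.W.grad += (dy2.T @ cols2).reshape(self.W.data.shape)
        self.b.grad += dy2.sum(axis=0)
        dcols2 = dy2 @ self.W.data.reshape(self.c_out, -1)
        dcols = dcols2.reshape(N, Ho, Wo, C, k, k).transpose(0, 3, 4, 5, 1, 2)
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p))
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + s * Ho:s, kj:kj + s * Wo:s] += dcols[:, :, ki, kj]
        return dxp[:, :, p:p + H, p:p + W]


class ConvTranspose2d(Layer):
    """Transposed convolution (the adjoint of Conv2d), for up-sampling."""

    def __init__(self, c_in, c_out, kernel=4, stride=2, pad=1, rng=None):
        rng = rng or np.random.default_rng(0)
        self.k, self.s, self.p = kernel, stride, pad
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * kernel * kernel
        self.W = Param(_he_init(rng, (c_in, c_out, kernel, kernel), fan_in))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        N, C, H, W = x.shape
        k, s, p = self.k, self.s, self.p
        Ho = (H - 1) * s + k - 2 * p
        Wo = (W - 1) * s + k - 2 * p
        t = np.einsum("nchw,cfkl->nfklhw", x, self.W.data)
        yp = np.zeros((N, self.c_out, (H - 1) * s + k, (W - 1) * s + k))
        for ki in range(k):
            for kj in range(k):
                yp[:, :, ki:ki + s * H:s, kj:kj + s * W:s] += t[:, :, ki, kj]
        self._cache = (x, (Ho, Wo))
        y = yp[:, :, p:p + Ho, p:p + Wo]
        return y + self.b.data[None, :, None, None]

    def backward(self, dout):
        x, (Ho, Wo) = self._cache
        N, C, H, W = x.shape
        k, s, p = self.k, self.s, self.p
        dyp = np.zeros((N, self.c_out, (H - 1) * s + k, (W - 1) * s + k))
        dyp[:, :, p:p + Ho, p:p + Wo] = dout
        dt = np.empty((N, self.c_out, k, k, H, W))
        for ki in range(k):
            for kj in range(k):
                dt[:, :, ki, kj] = dyp[:, :, ki:ki + s * H:s, kj:kj + s * W:s]
        self.W.grad += np.einsum("nchw,nfklhw->cfkl", x, dt)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        return np.einsum("nfklhw,cfkl->nchw", dt, self.W.data)


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalization with learned affine."""

    def __init__(self, channels, eps=1e-5):
        self.eps = eps
        self.g = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))

    def params(self):
        return [self.g, self.beta]

    def forward(self, x, train=False):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        std = np.sqrt(var + self.eps)
        xhat = (x - mu) / std
        self._cache = (xhat, std)
        return self.g.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dout):
        xhat, std = self._cache
        self.g.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.g.data[None, :, None, None]
        m1 = dxhat.mean(axis=(2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        return (dxhat - m1 - xhat * m2) / std


class Linear(Layer):
    def __init__(self, n_in, n_out, rng=None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(_he_init(rng, (n_in, n_out), n_in))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.data.T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._m = x > 0
        return x * self._m

    def backward(self, dout):
        return dout * self._m


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        self.slope = slope

    def forward(self, x, train=False):
        self._m = x > 0
        return np.where(self._m, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._m, dout, self.slope * dout)


class Tanh(Layer):
    def forward(self, x, train=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y**2)


class Dropout(Layer):
    """Inverted dropout; active only when ``train=True``."""

    def __init__(self, rate, rng=None):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        N, C, H, W = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (H * W)


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class ResidualBlock(Layer):
    """Two 3x3 convolutions with an identity skip (normalization-free)."""

    def __init__(self, channels, rng=None):
        self.conv1 = Conv2d(channels, channels, 3, 1, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(channels, channels, 3, 1, rng=rng)
        self.relu_out = ReLU()
        # scale the second conv down so the residual branch starts small
        self.conv2.W.data *= 0.1

    def params(self):
        return self.conv1.params() + self.conv2.params()

    def forward(self, x, train=False):
        h = self.conv2.forward(self.relu1.forward(self.conv1.forward(x, train), train), train)
        return self.relu_out.forward(x + h, train)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        dh = self.conv1.backward(self.relu1.backward(self.conv2.backward(d)))
        return d + dh


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def get_weights(net: Layer) -> list:
    return [p.data.copy() for p in net.params()]


def set_weights(net: Layer, weights: list) -> None:
    for p, w in zip(net.params(), weights):
        if p.data.shape != w.shape:
            raise ValueError(f"weight shape mismatch: {p.data.shape} vs {w.shape}")
        p.data[...] = w
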