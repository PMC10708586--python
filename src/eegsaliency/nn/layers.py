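"""Minimal neural-network layers with explicit backward passes.

Each layer owns its parameters (``params``) and, after a backward call, the
matching gradients (``grads``).  Shapes exclude the batch axis; 4-D data is
NCHW.  The framework is intentionally small: it covers exactly the layer
vocabulary of the EEG classifier and the two GANs (dense, 2-D convolution,
transposed convolution, batch normalisation, dropout, leaky rectifier,
sigmoid, log-softmax, flatten/reshape) and nothing else.
"""

from __future__ import annotations

import numpy as np

from .core import conv2d_backward, conv2d_forward, dilate, same_pad, undilate


def _pair(v):
    return tuple(v) if isinstance(v, (tuple, list)) else (v, v)


class Layer:
    """Base class; subclasses implement init/forward/backward."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.training = False

    def init(self, rng, in_shape, dtype):
        return in_shape

    def forward(self, x):
        raise NotImplementedError

    def backward(self, gy):
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def describe(self) -> str:
        return type(self).__name__


def _uniform_init(rng, shape, fan_in, dtype):
    a = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-a, a, size=shape).astype(dtype)


class Dense(Layer):
    def __init__(self, units: int, bias: bool = True):
        super().__init__()
        self.units = units
        self.bias = bias

    def init(self, rng, in_shape, dtype):
        (fan_in,) = in_shape
        self.params["w"] = _uniform_init(rng, (fan_in, self.units), fan_in, dtype)
        if self.bias:
            self.params["b"] = np.zeros(self.units, dtype=dtype)
        return (self.units,)

    def forward(self, x):
        self._x = x
        y = x @ self.params["w"]
        if self.bias:
            y = y + self.params["b"]
        return y

    def backward(self, gy):
        self.grads["w"] = self._x.T @ gy
        if self.bias:
            self.grads["b"] = gy.sum(axis=0)
        return gy @ self.params["w"].T

    def describe(self):
        return f"Dense({self.units}, bias={self.bias})"


class Conv2d(Layer):
    """Cross-correlation over the two trailing axes of NCHW input."""

    def __init__(self, out_channels, kernel, stride=1, padding="same", bias=False):
        super().__init__()
        self.out_channels = out_channels
        self.kernel = _pair(kernel)
        self.stride = _pair(stride)
        self.padding = padding
        self.bias = bias

    def init(self, rng, in_shape, dtype):
        c, h, w = in_shape
        kh, kw = self.kernel
        fan_in = c * kh * kw
        self.params["w"] = _uniform_init(
            rng, (self.out_channels, c, kh, kw), fan_in, dtype
        )
        if self.bias:
            self.params["b"] = np.zeros(self.out_channels, dtype=dtype)
        if self.padding == "same":
            self.pad = (same_pad(h, kh, self.stride[0]), same_pad(w, kw, self.stride[1]))
        elif self.padding == "valid":
            self.pad = ((0, 0), (0, 0))
        else:
            raise ValueError(f"unknown padding {self.padding!r}")
        ho = (h + sum(self.pad[0]) - kh) // self.stride[0] + 1
        wo = (w + sum(self.pad[1]) - kw) // self.stride[1] + 1
        return (self.out_channels, ho, wo)

    def forward(self, x):
        y, self._cache = conv2d_forward(x, self.params["w"], self.stride, self.pad)
        if self.bias:
            y = y + self.params["b"][None, :, None, None]
        return y

    def backward(self, gy):
        gx, gw = conv2d_backward(gy, self._cache)
        self.grads["w"] = gw
        if self.bias:
            self.grads["b"] = gy.sum(axis=(0, 2, 3))
        return gx

    def describe(self):
        return (
            f"Conv2d({self.out_channels}, k={self.kernel}, s={self.stride}, "
            f"{self.padding}, bias={self.bias})"
        )


class ConvTranspose2d(Layer):
    """Learnable upsampling: output spatial size = input size x stride.

    Implemented as zero-insertion dilation followed by a stride-1
    correlation with the flipped kernel, padded by (stride + kernel - 2)
    per axis so the output is exactly ``in * stride``.
    """

    def __init__(self, out_channels, kernel, stride=1, bias=False):
        super().__init__()
        self.out_channels = out_channels
        self.kernel = _pair(kernel)
        self.stride = _pair(stride)
        self.bias = bias

    def init(self, rng, in_shape, dtype):
        c, h, w = in_shape
        kh, kw = self.kernel
        self.params["w"] = _uniform_init(
            rng, (c, self.out_channels, kh, kw), c * kh * kw, dtype
        )
        if self.bias:
            self.params["b"] = np.zeros(self.out_channels, dtype=dtype)
        self.pad = tuple(
            (t // 2, t - t // 2)
            for t in (
                self.stride[0] + kh - 2,
                self.stride[1] + kw - 2,
            )
        )
        return (self.out_channels, h * self.stride[0], w * self.stride[1])

    def forward(self, x):
        xd = dilate(x, self.stride)
        wt = self.params["w"][:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        y, self._cache = conv2d_forward(xd, wt, (1, 1), self.pad)
        if self.bias:
            y = y + self.params["b"][None, :, None, None]
        return y

    def backward(self, gy):
        gxd, gwt = conv2d_backward(gy, self._cache)
        self.grads["w"] = gwt.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
        if self.bias:
            self.grads["b"] = gy.sum(axis=(0, 2, 3))
        return undilate(gxd, self.stride)

    def describe(self):
        return (
            f"ConvTranspose2d({self.out_channels}, k={self.kernel}, "
            f"s={self.stride}, bias={self.bias})"
        )


class BatchNorm(Layer):
    """Normalise each feature over the batch: (y - mu_B) / sqrt(var_B + eps).

    No learned affine by default.  For NCHW input the feature axis is the
    channel axis and statistics pool over batch and space; for (N, F) input
    they pool over the batch.  Inference uses running averages accumulated
    with the given momentum.
    """

    def __init__(self, eps: float = 1e-5, momentum: float = 0.9, affine: bool = False):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.affine = affine

    def init(self, rng, in_shape, dtype):
        n_feat = in_shape[0]
        self.running_mean = np.zeros(n_feat, dtype=dtype)
        self.running_var = np.ones(n_feat, dtype=dtype)
        if self.affine:
            self.params["gamma"] = np.ones(n_feat, dtype=dtype)
            self.params["beta"] = np.zeros(n_feat, dtype=dtype)
        return in_shape

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0, 2, 3)

    def _expand(self, v, x):
        return v if x.ndim == 2 else v[None, :, None, None]

    def forward(self, x):
        axes = self._axes(x)
        if self.training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - self._expand(mu, x)) / self._expand(std, x)
        self._xhat, self._std, self._train_stats = xhat, std, self.training
        if self.affine:
            return self._expand(self.params["gamma"], x) * xhat + self._expand(
                self.params["beta"], x
            )
        return xhat

    def backward(self, gy):
        xhat, std = self._xhat, self._std
        axes = self._axes(gy)
        if self.affine:
            self.grads["gamma"] = (gy * xhat).sum(axis=axes)
            self.grads["beta"] = gy.sum(axis=axes)
            gy = gy * self._expand(self.params["gamma"], gy)
        if not self._train_stats:
            return gy / self._expand(std, gy)
        m = gy.size // gy.shape[1] if gy.ndim == 4 else gy.shape[0]
        g_mean = self._expand(gy.mean(axis=axes), gy)
        gx_mean = self._expand((gy * xhat).mean(axis=axes), gy)
        return (gy - g_mean - xhat * gx_mean) / self._expand(std, gy)

    def describe(self):
        return f"BatchNorm(eps={self.eps}, affine={self.affine})"


class Dropout(Layer):
    """Inverted dropout: zero with probability p, rescale survivors by 1/(1-p)."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def init(self, rng, in_shape, dtype):
        self._rng = np.random.default_rng(rng.integers(2**31))
        return in_shape

    def forward(self, x):
        if not self.training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self._rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask

    def describe(self):
        return f"Dropout({self.rate})"


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.1):
        super().__init__()
        self.alpha = alpha

    def forward(self, x):
        self._neg = x < 0
        return np.where(self._neg, self.alpha * x, x)

    def backward(self, gy):
        return np.where(self._neg, self.alpha * gy, gy)

    def describe(self):
        return f"LeakyReLU({self.alpha})"


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, gy):
        return gy * self._y * (1.0 - self._y)


class LogSoftmax(Layer):
    def forward(self, x):
        z = x - x.max(axis=1, keepdims=True)
        self._y = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        return self._y

    def backward(self, gy):
        return gy - np.exp(self._y) * gy.sum(axis=1, keepdims=True)


class Flatten(Layer):
    def init(self, rng, in_shape, dtype):
        self._in = in_shape
        return (int(np.prod(in_shape)),)

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape):
        super().__init__()
        self.shape = tuple(shape)

    def init(self, rng, in_shape, dtype):
        if int(np.prod(in_shape)) != int(np.prod(self.shape)):
            raise ValueError(f"cannot reshape {in_shape} to {self.shape}")
        self._in = in_shape
        return self.shape

    def forward(self, x):
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, gy):
        return gy.reshape((gy.shape[0],) + self._in)

    def describe(self):
        return f"Reshape{self.shape}"
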