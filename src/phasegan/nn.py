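"""Minimal numpy neural-network engine used by the three-player model.

Implements exactly the building blocks the spectral networks need — 2-D
convolution and transposed convolution with 4x4 kernels, stride 2 and
"same" padding, batch normalization, leaky ReLU / tanh, dense layers, label
embeddings, softmax cross-entropy, and Adam — with hand-written
reverse-mode gradients.  All arrays are float64 and the layout is
(batch, channels, height, width).

Transposed convolution is defined as the exact adjoint of the forward
convolution between the same pair of spatial shapes, so a generator can
mirror any discriminator downsampling path shape-for-shape even when the
grid sizes are odd.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Param", "Dense", "Conv2D", "ConvTranspose2D", "BatchNorm2D",
           "LeakyReLU", "Tanh", "Flatten", "Embedding", "Sequential", "Adam",
           "softmax", "cross_entropy", "conv_output_shape"]


class Param:
    """A trainable array together with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


def conv_output_shape(shape: tuple[int, int], stride: int = 2) -> tuple[int, int]:
    """Spatial output shape of a stride-s "same" convolution (ceil division)."""
    return (math.ceil(shape[0] / stride), math.ceil(shape[1] / stride))


class _ConvGeometry:
    """Padding/stride bookkeeping for one (in_shape -> out_shape) conv."""

    def __init__(self, in_shape, k, stride):
        self.h, self.w = in_shape
        self.k, self.s = k, stride
        self.oh, self.ow = conv_output_shape(in_shape, stride)
        pad_h = max((self.oh - 1) * stride + k - self.h, 0)
        pad_w = max((self.ow - 1) * stride + k - self.w, 0)
        self.pt, self.pb = pad_h // 2, pad_h - pad_h // 2
        self.pl, self.pr = pad_w // 2, pad_w - pad_w // 2

    def pad(self, x):
        return np.pad(x, ((0, 0), (0, 0), (self.pt, self.pb), (self.pl, self.pr)))

    def crop(self, xp):
        return xp[:, :, self.pt:self.pt + self.h, self.pl:self.pl + self.w]


def _conv_fwd(xp, weight, g: _ConvGeometry):
    """xp: padded input (B, Cin, Hp, Wp); weight (Cout, Cin, k, k)."""
    b = xp.shape[0]
    out = np.zeros((b, weight.shape[0], g.oh, g.ow))
    for ki in range(g.k):
        for kj in range(g.k):
            xs = xp[:, :, ki:ki + g.s * g.oh:g.s, kj:kj + g.s * g.ow:g.s]
            out += np.einsum("bihw,oi->bohw", xs, weight[:, :, ki, kj],
                             optimize=True)
    return out


def _conv_bwd_input(gout, weight, g: _ConvGeometry):
    """Gradient w.r.t. the *padded* input."""
    b = gout.shape[0]
    gp = np.zeros((b, weight.shape[1], g.h + g.pt + g.pb, g.w + g.pl + g.pr))
    for ki in range(g.k):
        for kj in range(g.k):
            gp[:, :, ki:ki + g.s * g.oh:g.s, kj:kj + g.s * g.ow:g.s] += np.einsum(
                "bohw,oi->bihw", gout, weight[:, :, ki, kj], optimize=True)
    return gp


def _conv_bwd_weight(xp, gout, g: _ConvGeometry, k_shape):
    gw = np.zeros(k_shape)
    for ki in range(g.k):
        for kj in range(g.k):
            xs = xp[:, :, ki:ki + g.s * g.oh:g.s, kj:kj + g.s * g.ow:g.s]
            gw[:, :, ki, kj] = np.einsum("bohw,bihw->oi", gout, xs, optimize=True)
    return gw


class Layer:
    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


class Conv2D(Layer):
    """Stride-2 "same" 2-D convolution with a fixed input spatial shape."""

    def __init__(self, cin, cout, in_shape, rng, k=4, stride=2, init_sd=0.02):
        self.geom = _ConvGeometry(in_shape, k, stride)
        self.weight = Param(rng.normal(0.0, init_sd, size=(cout, cin, k, k)))
        self.bias = Param(np.zeros(cout))
        self.out_shape = (self.geom.oh, self.geom.ow)
        self._xp = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=True):
        self._xp = self.geom.pad(x)
        out = _conv_fwd(self._xp, self.weight.value, self.geom)
        return out + self.bias.value[None, :, None, None]

    def backward(self, gout):
        self.weight.grad += _conv_bwd_weight(self._xp, gout, self.geom,
                                             self.weight.value.shape)
        self.bias.grad += gout.sum(axis=(0, 2, 3))
        return self.geom.crop(_conv_bwd_input(gout, self.weight.value, self.geom))


class ConvTranspose2D(Layer):
    """Adjoint of a stride-2 "same" convolution mapping out_shape -> in_shape.

    Maps (B, cin, *in_shape) to (B, cout, *out_shape) where
    ``conv_output_shape(out_shape) == in_shape``; this is the exact mirror
    of the discriminator's downsampling, including odd grid sizes.
    """

    def __init__(self, cin, cout, in_shape, out_shape, rng, k=4, stride=2,
                 init_sd=0.02):
        if conv_output_shape(out_shape, stride) != tuple(in_shape):
            raise ValueError(f"out_shape {out_shape} does not downsample to {in_shape}")
        self.geom = _ConvGeometry(out_shape, k, stride)
        # weight stored in conv orientation: (cin, cout, k, k) == (Cout_conv, Cin_conv)
        self.weight = Param(rng.normal(0.0, init_sd, size=(cin, cout, k, k)))
        self.bias = Param(np.zeros(cout))
        self.out_shape = tuple(out_shape)
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=True):
        self._x = x
        out = self.geom.crop(_conv_bwd_input(x, self.weight.value, self.geom))
        return out + self.bias.value[None, :, None, None]

    def backward(self, gout):
        gp = self.geom.pad(gout)
        self.weight.grad += _conv_bwd_weight(gp, self._x, self.geom,
                                             self.weight.value.shape)
        self.bias.grad += gout.sum(axis=(0, 2, 3))
        return _conv_fwd(gp, self.weight.value, self.geom)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng, init_sd=0.02):
        self.weight = Param(rng.normal(0.0, init_sd, size=(n_in, n_out)))
        self.bias = Param(np.zeros(n_out))
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, gout):
        self.weight.grad += self._x.T @ gout
        self.bias.grad += gout.sum(axis=0)
        return gout @ self.weight.value.T


class Embedding(Layer):
    """Learned per-class vectors for label conditioning."""

    def __init__(self, n_classes, dim, rng, init_sd=0.02):
        self.weight = Param(rng.normal(0.0, init_sd, size=(n_classes, dim)))
        self._ids = None

    def params(self):
        return [self.weight]

    def forward(self, ids, train=True):
        self._ids = np.asarray(ids, dtype=int)
        return self.weight.value[self._ids]

    def backward(self, gout):
        np.add.at(self.weight.grad, self._ids, gout)
        return None


class BatchNorm2D(Layer):
    def __init__(self, channels, momentum=0.9, eps=1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            axes = (0, 2, 3)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            n = x.shape[0] * x.shape[2] * x.shape[3]
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
            n = None
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        self._cache = (xhat, invstd, n, train)
        return self.gamma.value[None, :, None, None] * xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, gout):
        xhat, invstd, n, train = self._cache
        axes = (0, 2, 3)
        self.gamma.grad += (gout * xhat).sum(axis=axes)
        self.beta.grad += gout.sum(axis=axes)
        gxhat = gout * self.gamma.value[None, :, None, None]
        if not train:
            return gxhat * invstd[None, :, None, None]
        mean_g = gxhat.mean(axis=axes)
        mean_gx = (gxhat * xhat).mean(axis=axes)
        return invstd[None, :, None, None] * (
            gxhat - mean_g[None, :, None, None]
            - xhat * mean_gx[None, :, None, None])


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        self.slope = slope
        self._mask = None

    def forward(self, x, train=True):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gout):
        return np.where(self._mask, gout, self.slope * gout)


class Tanh(Layer):
    def __init__(self):
        self._y = None

    def forward(self, x, train=True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, gout):
        return gout * (1.0 - self._y ** 2)


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gout):
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout


class Adam:
    """Adam optimizer (the Table-style defaults live in the model config)."""

    def __init__(self, params: list[Param], lr=2e-4, beta1=0.5, beta2=0.9, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (p.grad - m)
            v += (1 - self.b2) * (p.grad ** 2 - v)
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, target_idx: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    target_idx = np.asarray(target_idx, dtype=int)
    p = softmax(logits)
    b = logits.shape[0]
    eps = 1e-12
    loss = -np.mean(np.log(p[np.arange(b), target_idx] + eps))
    grad = p.copy()
    grad[np.arange(b), target_idx] -= 1.0
    return loss, grad / b
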