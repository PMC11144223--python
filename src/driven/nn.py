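"""Minimal 1-D neural-network engine on numpy.

Implements exactly the layer set needed by the per-channel feature
extractors: 1-D (depthwise) convolutions, batch normalisation, SiLU,
squeeze-and-excitation, global average pooling, dense layers, dropout,
fused-MBConv / MBConv blocks, Adam, and softmax cross-entropy — each with
an explicit backward pass.  All state is numpy arrays and all randomness
flows through explicit generators, so training is bit-reproducible.

Shapes follow the (batch, channels, length) convention throughout.
"""

from __future__ import annotations

import copy

import numpy as np


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _same_pad(length: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """TF-style 'same' padding: output length ceil(L / stride)."""
    out = -(-length // stride)
    total = max((out - 1) * stride + kernel - length, 0)
    left = total // 2
    return out, left, total - left


def _windows(xp: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    """(N, C, Lp) -> (N, C, Lout, K) view of sliding windows."""
    w = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=2)
    return w[:, :, ::stride, :]


class Conv1d(Layer):
    def __init__(self, c_in, c_out, kernel=3, stride=1, rng=None, bias=False):
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel))
        self.w = Param(w)
        self.b = Param(np.zeros(c_out)) if bias else None
        self.kernel, self.stride = kernel, stride

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=False):
        n, c, length = x.shape
        out, pl, pr = _same_pad(length, self.kernel, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        cols = _windows(xp, self.kernel, self.stride)  # (N, C, Lout, K)
        y = np.einsum("nclk,ock->nol", cols, self.w.value, optimize=True)
        if self.b is not None:
            y += self.b.value[None, :, None]
        self._cache = (cols, xp.shape, pl, length)
        return y

    def backward(self, g):
        cols, xp_shape, pl, length = self._cache
        self.w.grad += np.einsum("nol,nclk->ock", g, cols, optimize=True)
        if self.b is not None:
            self.b.grad += g.sum(axis=(0, 2))
        dcols = np.einsum("nol,ock->nclk", g, self.w.value, optimize=True)
        dxp = np.zeros(xp_shape)
        l_out = g.shape[2]
        for j in range(self.kernel):
            dxp[:, :, j : j + self.stride * l_out : self.stride] += dcols[..., j]
        return dxp[:, :, pl : pl + length]


class DepthwiseConv1d(Layer):
    def __init__(self, channels, kernel=3, stride=1, rng=None):
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / kernel), size=(channels, kernel))
        self.w = Param(w)
        self.kernel, self.stride = kernel, stride

    def params(self):
        return [self.w]

    def forward(self, x, train=False):
        n, c, length = x.shape
        out, pl, pr = _same_pad(length, self.kernel, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        cols = _windows(xp, self.kernel, self.stride)  # (N, C, Lout, K)
        y = np.einsum("nclk,ck->ncl", cols, self.w.value, optimize=True)
        self._cache = (cols, xp.shape, pl, length)
        return y

    def backward(self, g):
        cols, xp_shape, pl, length = self._cache
        self.w.grad += np.einsum("ncl,nclk->ck", g, cols, optimize=True)
        dcols = np.einsum("ncl,ck->nclk", g, self.w.value, optimize=True)
        dxp = np.zeros(xp_shape)
        l_out = g.shape[2]
        for j in range(self.kernel):
            dxp[:, :, j : j + self.stride * l_out : self.stride] += dcols[..., j]
        return dxp[:, :, pl : pl + length]


class BatchNorm1d(Layer):
    def __init__(self, channels, momentum=0.9, eps=1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, g):
        xhat, inv, shape = self._cache
        n_eff = shape[0] * shape[2]
        self.gamma.grad += (g * xhat).sum(axis=(0, 2))
        self.beta.grad += g.sum(axis=(0, 2))
        gh = g * self.gamma.value[None, :, None]
        # standard batchnorm backward over (N, L) per channel
        t1 = gh.sum(axis=(0, 2), keepdims=True)
        t2 = (gh * xhat).sum(axis=(0, 2), keepdims=True)
        return inv[None, :, None] * (gh - t1 / n_eff - xhat * t2 / n_eff)


def _silu(x):
    s = 1.0 / (1.0 + np.exp(-x))
    return x * s, s


class SiLU(Layer):
    def forward(self, x, train=False):
        y, s = _silu(x)
        self._cache = (x, s)
        return y

    def backward(self, g):
        x, s = self._cache
        return g * (s * (1.0 + x * (1.0 - s)))


class Dense(Layer):
    def __init__(self, n_in, n_out, rng=None):
        rng = rng or np.random.default_rng()
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        self._cache = x
        return x @ self.w.value + self.b.value

    def backward(self, g):
        x = self._cache
        self.w.grad += x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.w.value.T


class GlobalAvgPool(Layer):
    """(N, C, L) -> (N, C)."""

    def forward(self, x, train=False):
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, g):
        return np.repeat(g[:, :, None], self._length, axis=2) / self._length


class Dropout(Layer):
    def __init__(self, p, rng):
        self.p = p
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class SEBlock(Layer):
    """Squeeze-and-excitation: channel gating from globally pooled activations."""

    def __init__(self, channels, reduced, rng=None):
        rng = rng or np.random.default_rng()
        self.w1 = Param(rng.normal(0.0, np.sqrt(2.0 / channels), size=(channels, reduced)))
        self.b1 = Param(np.zeros(reduced))
        self.w2 = Param(rng.normal(0.0, np.sqrt(2.0 / reduced), size=(reduced, channels)))
        self.b2 = Param(np.zeros(channels))

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2]

    def forward(self, x, train=False):
        z = x.mean(axis=2)  # (N, C)
        a = z @ self.w1.value + self.b1.value
        h, s_h = _silu(a)
        u = h @ self.w2.value + self.b2.value
        gate = 1.0 / (1.0 + np.exp(-u))  # (N, C)
        self._cache = (x, z, a, s_h, h, gate)
        return x * gate[:, :, None]

    def backward(self, g):
        x, z, a, s_h, h, gate = self._cache
        length = x.shape[2]
        dgate = (g * x).sum(axis=2)
        du = dgate * gate * (1.0 - gate)
        self.w2.grad += h.T @ du
        self.b2.grad += du.sum(axis=0)
        dh = du @ self.w2.value.T
        da = dh * (s_h * (1.0 + a * (1.0 - s_h)))
        self.w1.grad += z.T @ da
        self.b1.grad += da.sum(axis=0)
        dz = da @ self.w1.value.T
        return g * gate[:, :, None] + dz[:, :, None] / length


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class Residual(Layer):
    """Identity shortcut around a body; used only when shapes are preserved."""

    def __init__(self, body: Layer):
        self.body = body

    def params(self):
        return self.body.params()

    def forward(self, x, train=False):
        return x + self.body.forward(x, train)

    def backward(self, g):
        return g + self.body.backward(g)


def fused_mbconv(c_in, c_out, stride, expand, rng):
    """Fused-MBConv: k3 conv (expand) + optional 1x1 projection."""
    mid = c_in * expand
    if expand == 1:
        body = Sequential(
            Conv1d(c_in, c_out, 3, stride, rng),
            BatchNorm1d(c_out),
            SiLU(),
        )
    else:
        body = Sequential(
            Conv1d(c_in, mid, 3, stride, rng),
            BatchNorm1d(mid),
            SiLU(),
            Conv1d(mid, c_out, 1, 1, rng),
            BatchNorm1d(c_out),
        )
    if stride == 1 and c_in == c_out:
        return Residual(body)
    return body


def mbconv(c_in, c_out, stride, expand, rng, se_ratio=0.25):
    """MBConv: 1x1 expand, depthwise k3, squeeze-excite, 1x1 project."""
    mid = c_in * expand
    reduced = max(1, int(c_in * se_ratio))
    body = Sequential(
        Conv1d(c_in, mid, 1, 1, rng),
        BatchNorm1d(mid),
        SiLU(),
        DepthwiseConv1d(mid, 3, stride, rng),
        BatchNorm1d(mid),
        SiLU(),
        SEBlock(mid, reduced, rng),
        Conv1d(mid, c_out, 1, 1, rng),
        BatchNorm1d(c_out),
    )
    if stride == 1 and c_in == c_out:
        return Residual(body)
    return body


class Adam:
    def __init__(self, params: list[Param], lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
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
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean categorical cross-entropy and its gradient w.r.t. logits.

    labels are integer class indices.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = -np.mean(np.log(probs[np.arange(n), labels] + 1e-300))
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def clone_param_values(params: list[Param]) -> list[np.ndarray]:
    return [p.value.copy() for p in params]


def restore_param_values(params: list[Param], values: list[np.ndarray]) -> None:
    for p, v in zip(params, values):
        p.value[...] = v


def snapshot_state(layers: Layer) -> dict:
    """Deep copy of every trainable value plus batchnorm running stats."""
    return copy.deepcopy(
        {
            "params": [p.value for p in layers.params()],
            "bn": [
                (bn.running_mean, bn.running_var)
                for bn in _iter_batchnorms(layers)
            ],
        }
    )


def restore_state(layers: Layer, state: dict) -> None:
    for p, v in zip(layers.params(), state["params"]):
        p.value[...] = v
    for bn, (rm, rv) in zip(_iter_batchnorms(layers), state["bn"]):
        bn.running_mean[...] = rm
        bn.running_var[...] = rv


def _iter_batchnorms(layer: Layer):
    if isinstance(layer, BatchNorm1d):
        yield layer
    for child in getattr(layer, "layers", []):
        yield from _iter_batchnorms(child)
    body = getattr(layer, "body", None)
    if body is not None:
        yield from _iter_batchnorms(body)
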