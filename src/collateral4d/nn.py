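"""Minimal numpy neural-network layer stack with hand-written backprop.

Implements exactly the pieces the residual classifier needs: 2-D
convolution (shifted-slice matmul formulation, no im2col buffer), batch
normalisation, ReLU, 3x3 max pooling, global average pooling, a linear
head, softmax cross-entropy, and the Adam optimiser.  All tensors are
float32 NCHW; initialisation is seeded through a numpy Generator.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, stride s, zero padding p, no bias (every conv
    is followed by batch norm)."""

    def __init__(self, cin, cout, k, stride, pad, rng):
        fan_in = cin * k * k
        std = np.sqrt(2.0 / fan_in)
        self.w = Param(rng.normal(0.0, std, size=(cout, cin, k, k)))
        self.k, self.stride, self.pad = k, stride, pad
        self._xp = None

    def params(self):
        return [self.w]

    def _out_hw(self, h, w):
        k, s, p = self.k, self.stride, self.pad
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def forward(self, x, train):
        k, s, p = self.k, self.stride, self.pad
        n, cin, h, w = x.shape
        oh, ow = self._out_hw(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._xp = xp if train else None
        self._in_hw = (h, w)
        W = self.w.value
        cout = W.shape[0]
        out = np.zeros((cout, n, oh, ow), dtype=np.float32)
        for ky in range(k):
            for kx in range(k):
                xs = xp[:, :, ky : ky + (oh - 1) * s + 1 : s, kx : kx + (ow - 1) * s + 1 : s]
                # (cout, cin) x (n, cin, oh, ow) -> (cout, n, oh, ow)
                out += np.tensordot(W[:, :, ky, kx], xs, axes=([1], [1]))
        return np.ascontiguousarray(out.transpose(1, 0, 2, 3))

    def backward(self, grad):
        k, s, p = self.k, self.stride, self.pad
        xp = self._xp
        n, _, oh, ow = grad.shape
        W = self.w.value
        dxp = np.zeros_like(xp)
        g = grad.transpose(1, 0, 2, 3)  # (cout, n, oh, ow)
        for ky in range(k):
            for kx in range(k):
                xs = xp[:, :, ky : ky + (oh - 1) * s + 1 : s, kx : kx + (ow - 1) * s + 1 : s]
                self.w.grad[:, :, ky, kx] += np.tensordot(g, xs, axes=([1, 2, 3], [0, 2, 3]))
                dslice = np.tensordot(W[:, :, ky, kx], g, axes=([0], [0]))  # (cin,n,oh,ow)
                dxp[:, :, ky : ky + (oh - 1) * s + 1 : s, kx : kx + (ow - 1) * s + 1 : s] += (
                    dslice.transpose(1, 0, 2, 3)
                )
        self._xp = None
        h, w = self._in_hw
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d(Layer):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = Param(np.ones(c, dtype=np.float32))
        self.beta = Param(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad):
        xhat, inv, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        gxhat = grad * self.gamma.value[None, :, None, None]
        # standard batch-norm gradient
        dx = (
            gxhat
            - gxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[None, :, None, None]
        self._cache = None
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train):
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, 0.0).astype(np.float32)

    def backward(self, grad):
        out = grad * self._mask
        self._mask = None
        return out


class MaxPool2d(Layer):
    """k x k max pooling with stride and zero-boundary padding by -inf."""

    def __init__(self, k=3, stride=2, pad=1):
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x, train):
        k, s, p = self.k, self.stride, self.pad
        n, c, h, w = x.shape
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        xp = np.full((n, c, h + 2 * p, w + 2 * p), -np.inf, dtype=np.float32)
        xp[:, :, p : p + h, p : p + w] = x
        stack = np.stack(
            [
                xp[:, :, ky : ky + (oh - 1) * s + 1 : s, kx : kx + (ow - 1) * s + 1 : s]
                for ky in range(k)
                for kx in range(k)
            ]
        )
        arg = stack.argmax(axis=0)
        out = np.take_along_axis(stack, arg[None], axis=0)[0]
        if train:
            self._cache = (arg, (n, c, h, w))
        return out

    def backward(self, grad):
        k, s, p = self.k, self.stride, self.pad
        arg, (n, c, h, w) = self._cache
        oh, ow = grad.shape[2:]
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k * k):
            mask = arg == i
            if not mask.any():
                continue
            ky, kx = divmod(i, k)
            dxp[:, :, ky : ky + (oh - 1) * s + 1 : s, kx : kx + (ow - 1) * s + 1 : s] += (
                grad * mask
            )
        self._cache = None
        return dxp[:, :, p : p + h, p : p + w]


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        h, w = self._hw
        return np.broadcast_to(
            grad[:, :, None, None] / (h * w), grad.shape + (h, w)
        ).astype(np.float32)


class Linear(Layer):
    def __init__(self, cin, cout, rng, zero_init=False):
        if zero_init:
            w = np.zeros((cout, cin))
        else:
            w = rng.normal(0.0, np.sqrt(1.0 / cin), size=(cout, cin))
        self.w = Param(w)
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad):
        self.w.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        out = grad @ self.w.value
        self._x = None
        return out


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    p = softmax(logits.astype(np.float64))
    n = len(labels)
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)


class Adam:
    def __init__(self, params: list[Param], lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
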