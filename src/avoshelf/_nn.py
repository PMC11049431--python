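"""Minimal numpy neural-network engine for the stage classifier.

Just enough machinery for a small convolutional image classifier trained
on one CPU: Conv2D (im2col), ReLU, max-pool, dense layers, softmax
cross-entropy, and SGD with momentum.  Weights are plain numpy arrays so
checkpoints are trivial deep copies.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "Conv2D", "ReLU", "MaxPool2D", "Flatten", "Sequential",
           "softmax", "cross_entropy_grad", "SGDMomentum"]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(probs: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. logits."""
    n = len(labels)
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Layer:
    params: list  # list of numpy arrays (shared with grads by index)

    def forward(self, x, train=True):
        raise NotImplementedError

    def backward(self, gout):
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, gout):
        self.grads[0][...] = self._x.T @ gout
        self.grads[1][...] = gout.sum(axis=0)
        return gout @ self.params[0].T


def _im2col(x: np.ndarray, kh: int, kw: int):
    # x: (N, H, W, C) -> (N, H-kh+1, W-kw+1, kh*kw*C), valid convolution
    n, h, w, c = x.shape
    oh, ow = h - kh + 1, w - kw + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, shape=(n, oh, ow, kh, kw, c), strides=(s0, s1, s2, s1, s2, s3))
    return view.reshape(n, oh, ow, kh * kw * c)


class Conv2D(Layer):
    """Valid 2D convolution with 'same' output via reflect pre-padding."""

    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator):
        self.k = ksize
        scale = np.sqrt(2.0 / (ksize * ksize * c_in))
        W = rng.normal(0.0, scale, size=(ksize * ksize * c_in, c_out))
        self.params = [W, np.zeros(c_out)]
        self.grads = [np.zeros_like(W), np.zeros(c_out)]
        self.c_in = c_in

    def forward(self, x, train=True):
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)), mode="edge")
        self._cols = _im2col(xp, self.k, self.k)       # (N, H, W, k*k*Cin)
        self._xshape = x.shape
        return self._cols @ self.params[0] + self.params[1]

    def backward(self, gout):
        n, h, w, c_out = gout.shape
        cols2d = self._cols.reshape(-1, self._cols.shape[-1])
        g2d = gout.reshape(-1, c_out)
        self.grads[0][...] = cols2d.T @ g2d
        self.grads[1][...] = g2d.sum(axis=0)
        # gradient w.r.t. input via col2im
        gcols = (g2d @ self.params[0].T).reshape(n, h, w, self.k, self.k, self.c_in)
        p = self.k // 2
        gx = np.zeros((n, h + 2 * p, w + 2 * p, self.c_in))
        for i in range(self.k):
            for j in range(self.k):
                gx[:, i:i + h, j:j + w, :] += gcols[:, :, :, i, j, :]
        return gx[:, p:p + h, p:p + w, :]


class ReLU(Layer):
    params: list = []
    grads: list = []

    def forward(self, x, train=True):
        self._m = x > 0
        return x * self._m

    def backward(self, gout):
        return gout * self._m


class MaxPool2D(Layer):
    params: list = []
    grads: list = []

    def __init__(self, size: int = 2):
        self.s = size

    def forward(self, x, train=True):
        n, h, w, c = x.shape
        s = self.s
        hh, ww = h // s, w // s
        x = x[:, :hh * s, :ww * s, :]
        view = x.reshape(n, hh, s, ww, s, c)
        out = view.max(axis=(2, 4))
        self._mask = view == out[:, :, None, :, None, :]
        self._shape = (n, h, w, c)
        return out

    def backward(self, gout):
        n, h, w, c = self._shape
        s = self.s
        hh, ww = h // s, w // s
        g = self._mask * gout[:, :, None, :, None, :]
        gx = np.zeros((n, h, w, c))
        gx[:, :hh * s, :ww * s, :] = g.reshape(n, hh * s, ww * s, c)
        return gx


class Flatten(Layer):
    params: list = []
    grads: list = []

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(len(x), -1)

    def backward(self, gout):
        return gout.reshape(self._shape)


class Sequential:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, train=True):
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, gout):
        for lay in reversed(self.layers):
            gout = lay.backward(gout)
        return gout

    def get_weights(self):
        return [p.copy() for lay in self.layers for p in lay.params]

    def set_weights(self, weights):
        i = 0
        for lay in self.layers:
            for p in lay.params:
                p[...] = weights[i]
                i += 1

    def parameters(self):
        return ([p for lay in self.layers for p in lay.params],
                [g for lay in self.layers for g in lay.grads])


class SGDMomentum:
    def __init__(self, params, grads, lr: float, momentum: float = 0.9):
        self.params, self.grads = params, grads
        self.lr, self.momentum = lr, momentum
        self.vel = [np.zeros_like(p) for p in params]

    def step(self):
        for p, g, v in zip(self.params, self.grads, self.vel):
            v *= self.momentum
            v -= self.lr * g
            p += v
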