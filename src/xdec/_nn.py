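"""Minimal dense-network machinery: linear layers, activations, Adam.

The networks used here are small (a few dense layers), so forward and
backward passes are written out explicitly in NumPy.  Gradient correctness
is pinned down by finite-difference tests rather than an autodiff engine.
"""

from __future__ import annotations

import numpy as np


class Linear:
    """Dense layer y = xW + b with Glorot-uniform initialisation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gW += self._x.T @ grad
        self.gb += grad.sum(axis=0)
        return grad @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.gW, self.gb]

    def n_params(self) -> int:
        return self.W.size + self.b.size


def relu(x):
    return np.maximum(x, 0.0)


def relu_backward(grad, x):
    return grad * (x > 0)


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    """Adam over a flat list of parameter arrays, updated in place."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def zero_grads(layers) -> None:
    for layer in layers:
        layer.gW.fill(0.0)
        layer.gb.fill(0.0)


def collect_params(layers):
    params, grads = [], []
    for layer in layers:
        params.extend(layer.params)
        grads.extend(layer.grads)
    return params, grads


def minibatches(n: int, batch_size: int, rng: np.random.Generator):
    """Seeded shuffled minibatch index generator for one pass; the final
    short batch is used, not dropped."""
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]
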