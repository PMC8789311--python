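"""Stacked LSTM with full backpropagation-through-time, in NumPy.

The network is small by deep-learning standards (default two stacks of
100 tanh units over 100 timesteps), so a straightforward dense NumPy
implementation with hand-derived gradients is fast enough for the
package's desk-scale experiments and keeps the dependency surface to
NumPy alone.  Gates follow the standard parameterization

    z_t = [x_t, h_{t-1}] W + b,          z split into (i, f, g, o)
    c_t = sigmoid(f) * c_{t-1} + sigmoid(i) * tanh(g)
    h_t = sigmoid(o) * tanh(c_t)

with the forget-gate bias initialized to 1.  Dropout between stacks and
before the head uses inverted scaling with one mask per sequence shared
across timesteps, so the same machinery serves both regularization and
Monte-Carlo dropout at inference.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

__all__ = ["LSTMStack", "Dense", "sigmoid", "softmax"]


def sigmoid(x):
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


def softmax(x):
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


class Dense:
    """Linear layer applied to the last axis."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / n_in)
        self.W = rng.uniform(-scale, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        x = self._x
        self.dW = np.tensordot(x, dy, axes=(tuple(range(x.ndim - 1)),) * 2)
        self.db = dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        return dy @ self.W.T

    @property
    def grads(self):
        return [self.dW, self.db]


class LSTMStack:
    """One LSTM layer unrolled over time.

    ``forward(X)`` consumes ``(B, T, D)`` and returns hidden states
    ``(B, T, H)``; ``backward(dH)`` accepts the gradient w.r.t. every
    hidden state (zeros where a head does not read them) and returns the
    gradient w.r.t. the inputs.
    """

    def __init__(self, n_in: int, n_units: int, rng: np.random.Generator):
        self.n_in = n_in
        self.H = n_units
        scale = np.sqrt(1.0 / (n_in + n_units))
        self.W = rng.uniform(-scale, scale, size=(n_in + n_units, 4 * n_units))
        self.b = np.zeros(4 * n_units)
        self.b[n_units : 2 * n_units] = 1.0  # forget-gate bias

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, X):
        B, T, D = X.shape
        H = self.H
        self._X = X
        self._gates = np.zeros((B, T, 4 * H))
        self._C = np.zeros((B, T, H))
        self._Hs = np.zeros((B, T, H))
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        W, b = self.W, self.b
        for t in range(T):
            z = np.concatenate([X[:, t], h], axis=1) @ W + b
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = sigmoid(z[:, 3 * H :])
            c = f * c + i * g
            h = o * np.tanh(c)
            self._gates[:, t, :H] = i
            self._gates[:, t, H : 2 * H] = f
            self._gates[:, t, 2 * H : 3 * H] = g
            self._gates[:, t, 3 * H :] = o
            self._C[:, t] = c
            self._Hs[:, t] = h
        return self._Hs

    def backward(self, dH):
        X, gates, C, Hs = self._X, self._gates, self._C, self._Hs
        B, T, D = X.shape
        H = self.H
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        dX = np.zeros_like(X)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i = gates[:, t, :H]
            f = gates[:, t, H : 2 * H]
            g = gates[:, t, 2 * H : 3 * H]
            o = gates[:, t, 3 * H :]
            c = C[:, t]
            c_prev = C[:, t - 1] if t > 0 else np.zeros((B, H))
            h_prev = Hs[:, t - 1] if t > 0 else np.zeros((B, H))
            tanh_c = np.tanh(c)
            dh = dH[:, t] + dh_next
            dc = dc_next + dh * o * (1.0 - tanh_c**2)
            da_o = dh * tanh_c * o * (1.0 - o)
            da_i = dc * g * i * (1.0 - i)
            da_f = dc * c_prev * f * (1.0 - f)
            da_g = dc * i * (1.0 - g**2)
            dc_next = dc * f
            da = np.concatenate([da_i, da_f, da_g, da_o], axis=1)
            xt = np.concatenate([X[:, t], h_prev], axis=1)
            self.dW += xt.T @ da
            self.db += da.sum(axis=0)
            dxt = da @ self.W.T
            dX[:, t] = dxt[:, :D]
            dh_next = dxt[:, D:]
        return dX

    @property
    def grads(self):
        return [self.dW, self.db]


class Adam:
    """Adam with the conventional default hyperparameters."""

    def __init__(self, params: List[np.ndarray], lr=1e-3, beta1=0.9,
                 beta2=0.999, eps=1e-7, clipnorm: Optional[float] = 5.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.clipnorm = clipnorm
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]):
        if self.clipnorm is not None:
            norm = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
            if norm > self.clipnorm:
                grads = [g * (self.clipnorm / norm) for g in grads]
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)
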