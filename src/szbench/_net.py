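"""Minimal numpy neural-network layers with exact backprop.

Implements only what the single-channel classifier needs: 1-D convolution
with same padding, batch normalization, ReLU, non-overlapping max pooling,
a single-layer (bi)directional LSTM read out at its final hidden state,
dropout, a fully connected layer, and softmax cross-entropy.  Everything
is vectorized over the batch; gradients are validated against numerical
differentiation in the test suite.

Parameter initialisation mirrors the common fan-in uniform convention
U(-1/sqrt(fan_in), 1/sqrt(fan_in)); the LSTM keeps two bias vectors per
gate block (input-side and recurrent-side), the convention assumed by the
parameter-budget arithmetic.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np


class Layer:
    """Base: parameters and gradients live in dicts keyed per layer."""

    def params(self) -> Dict[str, np.ndarray]:
        return {}

    def grads(self) -> Dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv1dSame(Layer):
    """1-D convolution, stride 1, zero same-padding, odd kernel."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("same padding requires an odd kernel")
        self.kernel = kernel
        self.pad = (kernel - 1) // 2
        fan = c_in * kernel
        self.W = _uniform(rng, (c_out, c_in, kernel), fan)
        self.b = _uniform(rng, (c_out,), fan)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp: Optional[np.ndarray] = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, training):
        B, Cin, L = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        y = np.zeros((B, self.W.shape[0], L))
        for t in range(self.kernel):
            y += np.einsum("oi,bil->bol", self.W[:, :, t], xp[:, :, t:t + L],
                           optimize=True)
        y += self.b[None, :, None]
        self._xp = xp
        self._L = L
        return y

    def backward(self, dy):
        xp, L = self._xp, self._L
        self.db[:] = dy.sum(axis=(0, 2))
        dxp = np.zeros_like(xp)
        for t in range(self.kernel):
            self.dW[:, :, t] = np.einsum("bol,bil->oi", dy, xp[:, :, t:t + L],
                                         optimize=True)
            dxp[:, :, t:t + L] += np.einsum("oi,bol->bil", self.W[:, :, t], dy,
                                            optimize=True)
        return dxp[:, :, self.pad:self.pad + L]


class BatchNorm1d(Layer):
    """Per-channel normalization over (batch, time)."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.dgamma = np.zeros(c)
        self.dbeta = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.eps = eps
        self.momentum = momentum

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def forward(self, x, training):
        if training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv) if training else None
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dy):
        xhat, inv = self._cache
        self.dgamma[:] = (dy * xhat).sum(axis=(0, 2))
        self.dbeta[:] = dy.sum(axis=(0, 2))
        n = dy.shape[0] * dy.shape[2]
        g = self.gamma[None, :, None] * inv[None, :, None]
        mean_dy = dy.mean(axis=(0, 2))[None, :, None]
        mean_dyx = (dy * xhat).mean(axis=(0, 2))[None, :, None]
        return g * (dy - mean_dy - xhat * mean_dyx)


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool1d(Layer):
    """Non-overlapping pooling (kernel == stride)."""

    def __init__(self, kernel: int):
        self.kernel = kernel

    def forward(self, x, training):
        B, C, L = x.shape
        if L % self.kernel:
            raise ValueError(f"length {L} not divisible by pool {self.kernel}")
        xr = x.reshape(B, C, L // self.kernel, self.kernel)
        self._argmax = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, dy):
        B, C, L = self._shape
        k = self.kernel
        dx = np.zeros((B, C, L // k, k))
        np.put_along_axis(dx, self._argmax[..., None], dy[..., None], axis=3)
        return dx.reshape(B, C, L)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class _LstmDirection:
    """One direction of a single-layer LSTM, read out at the last step.

    Gate layout follows the i, f, g, o convention; two bias vectors are
    kept (they add, but are counted and stored separately).
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        h = hidden
        self.h = h
        self.Wx = _uniform(rng, (n_in, 4 * h), h)
        self.Wh = _uniform(rng, (h, 4 * h), h)
        self.b_ih = _uniform(rng, (4 * h,), h)
        self.b_hh = _uniform(rng, (4 * h,), h)
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db_ih = np.zeros_like(self.b_ih)
        self.db_hh = np.zeros_like(self.b_hh)

    def forward(self, x):  # x: (B, T, F) in processing order
        B, T, F = x.shape
        h = self.h
        hs = np.zeros((T + 1, B, h))
        cs = np.zeros((T + 1, B, h))
        gates: List[Tuple[np.ndarray, ...]] = []
        bias = self.b_ih + self.b_hh
        for t in range(T):
            z = x[:, t] @ self.Wx + hs[t] @ self.Wh + bias
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h:2 * h])
            g = np.tanh(z[:, 2 * h:3 * h])
            o = _sigmoid(z[:, 3 * h:])
            cs[t + 1] = f * cs[t] + i * g
            hs[t + 1] = o * np.tanh(cs[t + 1])
            gates.append((i, f, g, o))
        self._cache = (x, hs, cs, gates)
        return hs[T]

    def backward(self, dh_last):  # gradient w.r.t. final hidden state
        x, hs, cs, gates = self._cache
        B, T, F = x.shape
        h = self.h
        self.dWx[:] = 0
        self.dWh[:] = 0
        self.db_ih[:] = 0
        self.db_hh[:] = 0
        dx = np.zeros_like(x)
        dh = dh_last.copy()
        dc = np.zeros_like(dh_last)
        for t in range(T - 1, -1, -1):
            i, f, g, o = gates[t]
            tc = np.tanh(cs[t + 1])
            do = dh * tc * o * (1 - o)
            dc = dc + dh * o * (1 - tc ** 2)
            di = dc * g * i * (1 - i)
            df = dc * cs[t] * f * (1 - f)
            dg = dc * i * (1 - g ** 2)
            dz = np.concatenate([di, df, dg, do], axis=1)
            self.dWx += x[:, t].T @ dz
            self.dWh += hs[t].T @ dz
            self.db_ih += dz.sum(axis=0)
            self.db_hh += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.T
            dh = dz @ self.Wh.T
            dc = dc * f
        return dx


class BiLstmLast(Layer):
    """(Bi)directional single-layer LSTM returning final hidden state(s).

    Input (B, C, T) — conv channels become features, conv time steps the
    sequence.  Output (B, D*hidden), D = 2 when bidirectional.
    """

    def __init__(self, n_in: int, hidden: int, bidirectional: bool,
                 rng: np.random.Generator):
        self.fwd = _LstmDirection(n_in, hidden, rng)
        self.bwd = _LstmDirection(n_in, hidden, rng) if bidirectional else None

    def params(self):
        p = {f"fwd_{k}": v for k, v in vars(self.fwd).items()
             if k in ("Wx", "Wh", "b_ih", "b_hh")}
        if self.bwd is not None:
            p.update({f"bwd_{k}": getattr(self.bwd, k)
                      for k in ("Wx", "Wh", "b_ih", "b_hh")})
        return p

    def grads(self):
        g = {f"fwd_{k}": getattr(self.fwd, "d" + k)
             for k in ("Wx", "Wh", "b_ih", "b_hh")}
        if self.bwd is not None:
            g.update({f"bwd_{k}": getattr(self.bwd, "d" + k)
                      for k in ("Wx", "Wh", "b_ih", "b_hh")})
        return g

    def forward(self, x, training):
        seq = np.transpose(x, (0, 2, 1))  # (B, T, F)
        h_f = self.fwd.forward(seq)
        if self.bwd is None:
            return h_f
        h_b = self.bwd.forward(seq[:, ::-1])
        return np.concatenate([h_f, h_b], axis=1)

    def backward(self, dy):
        h = self.fwd.h
        if self.bwd is None:
            dseq = self.fwd.backward(dy)
        else:
            dseq = self.fwd.backward(dy[:, :h])
            dseq = dseq + self.bwd.backward(dy[:, h:])[:, ::-1]
        return np.transpose(dseq, (0, 2, 1))


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _uniform(rng, (n_in, n_out), n_in)
        self.b = _uniform(rng, (n_out,), n_in)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[:] = self._x.T @ dy
        self.db[:] = dy.sum(axis=0)
        return dy @ self.W.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    p = softmax(logits)
    B = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(B), y], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(B), y] -= 1.0
    return loss, dlogits / B


class Sequential:
    def __init__(self, layers: List[Layer]):
        self.layers = layers

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self) -> Dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params().items():
                out[f"{i}.{type(layer).__name__}.{k}"] = v
        return out

    def grads(self) -> Dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.grads().items():
                out[f"{i}.{type(layer).__name__}.{k}"] = v
        return out


class Adam:
    """Adam with the usual bias correction; state keyed like params()."""

    def __init__(self, params: Dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: Dict[str, np.ndarray]):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
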