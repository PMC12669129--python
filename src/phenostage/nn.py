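"""Minimal numpy neural-net backend for the leaf-pair regressor.

Implements exactly what the regression head needs and nothing more: 3x3
convolutions (computed as nine shifted tensor contractions, which is fast in
numpy for small feature maps), 2x2 max pooling, ReLU / LeakyReLU / GELU
activations, dense layers, inverted dropout, the Huber objective, and AdamW
(Adam with decoupled weight decay).  Everything is seeded and runs on a
single CPU; inputs are channels-last ``(N, H, W, C)`` float arrays.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "huber_terms",
    "huber_grad",
    "AdamW",
    "SmallConvNet",
    "build_model",
]


# ---------------------------------------------------------------------------
# Huber objective
# ---------------------------------------------------------------------------

def huber_terms(pred: np.ndarray, target: np.ndarray, delta: float) -> np.ndarray:
    """Per-sample Huber terms: 0.5*e^2 for |e| < delta, delta*(|e| - delta/2) otherwise."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    e = np.asarray(pred, dtype=np.float64) - np.asarray(target, dtype=np.float64)
    ae = np.abs(e)
    return np.where(ae < delta, 0.5 * e * e, delta * (ae - 0.5 * delta))


def huber_grad(pred: np.ndarray, target: np.ndarray, delta: float) -> np.ndarray:
    """d/dpred of the per-sample Huber term: e inside the knee, delta*sign(e) outside."""
    e = np.asarray(pred, dtype=np.float64) - np.asarray(target, dtype=np.float64)
    return np.where(np.abs(e) < delta, e, delta * np.sign(e))


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def _act(name: str):
    if name == "relu":
        fwd = lambda x: np.maximum(x, 0.0)
        bwd = lambda x, g: g * (x > 0)
    elif name == "leaky_relu":
        fwd = lambda x: np.where(x > 0, x, 0.01 * x)
        bwd = lambda x, g: g * np.where(x > 0, 1.0, 0.01)
    elif name == "gelu":
        c = math.sqrt(2.0 / math.pi)

        def fwd(x):
            return 0.5 * x * (1.0 + np.tanh(c * (x + 0.044715 * x**3)))

        def bwd(x, g):
            t = np.tanh(c * (x + 0.044715 * x**3))
            dt = (1.0 - t * t) * c * (1.0 + 3 * 0.044715 * x * x)
            return g * (0.5 * (1.0 + t) + 0.5 * x * dt)
    else:
        raise ValueError(f"unknown activation {name!r}")
    return fwd, bwd


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Conv3x3:
    """Same-padded 3x3 convolution, channels-last."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / (9 * c_in))
        self.w = rng.normal(0.0, scale, size=(3, 3, c_in, c_out))
        self.b = np.zeros(c_out)
        self._x = None

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def forward(self, x, train):
        n, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        out = np.broadcast_to(self.b, (n, h, w, self.w.shape[3])).copy()
        for di in range(3):
            for dj in range(3):
                out += xp[:, di : di + h, dj : dj + w, :] @ self.w[di, dj]
        self._x = xp
        return out

    def backward(self, g):
        xp = self._x
        n, hp, wp, _ = xp.shape
        h, w = hp - 2, wp - 2
        self.dw = np.empty_like(self.w)
        self.db = g.sum(axis=(0, 1, 2))
        dxp = np.zeros_like(xp)
        for di in range(3):
            for dj in range(3):
                patch = xp[:, di : di + h, dj : dj + w, :]
                self.dw[di, dj] = np.tensordot(patch, g, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, di : di + h, dj : dj + w, :] += g @ self.w[di, dj].T
        return dxp[:, 1:-1, 1:-1, :]

    def grads(self):
        return [self.dw, self.db]


class _MaxPool2:
    def params(self):
        return []

    def forward(self, x, train):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        self._mask = xr == out[:, :, None, :, None, :]
        # break ties: keep only the first max per window
        flat = self._mask.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
        first = np.cumsum(flat, axis=-1) == 1
        self._mask = (flat & first).reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        self._shape = x.shape
        return out

    def backward(self, g):
        n, h, w, c = self._shape
        gx = self._mask * g[:, :, None, :, None, :]
        return gx.reshape(n, h, w, c)

    def grads(self):
        return []


class _Activation:
    def __init__(self, name: str):
        self.fwd, self.bwd = _act(name)

    def params(self):
        return []

    def forward(self, x, train):
        self._x = x
        return self.fwd(x)

    def backward(self, g):
        return self.bwd(self._x, g)

    def grads(self):
        return []


class _Flatten:
    def params(self):
        return []

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)

    def grads(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, math.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.w + self.b

    def backward(self, g):
        self.dw = self._x.T @ g
        self.db = g.sum(axis=0)
        return g @ self.w.T

    def grads(self):
        return [self.dw, self.db]


class _Dropout:
    def __init__(self, p: float, rng: np.random.Generator):
        if not (0.0 <= p < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        self.p = p
        self.rng = rng

    def params(self):
        return []

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask

    def grads(self):
        return []


class _Residual:
    """Two 3x3 convs with an identity skip (pre-activation style)."""

    def __init__(self, c: int, activation: str, rng: np.random.Generator):
        self.conv1 = _Conv3x3(c, c, rng)
        self.act1 = _Activation(activation)
        self.conv2 = _Conv3x3(c, c, rng)
        self.act2 = _Activation(activation)

    def params(self):
        return self.conv1.params() + self.conv2.params()

    def forward(self, x, train):
        h = self.act1.forward(self.conv1.forward(x, train), train)
        h = self.conv2.forward(h, train)
        return self.act2.forward(h + x, train)

    def backward(self, g):
        g = self.act2.backward(g)
        gh = self.conv1.backward(self.act1.backward(self.conv2.backward(g)))
        return gh + g

    def grads(self):
        return self.conv1.grads() + self.conv2.grads()


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class SmallConvNet:
    """Sequential conv regressor mapping an image crop to one real value.

    ``small_conv``: four conv+pool blocks then a dense head with dropout.
    ``residual18``: a conv stem plus residual pairs per stage (18 weighted
    layers), same head; functional but much slower, provided for parity with
    larger-backbone configurations.
    """

    def __init__(self, input_side: int, backbone: str = "small_conv",
                 activation: str = "leaky_relu", dropout: float = 0.0, seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
        self.input_side = input_side
        layers: list = []
        side = input_side
        if backbone == "small_conv":
            c_prev = 3
            for c in (8, 16, 32, 32):
                if side < 2:
                    break
                layers += [_Conv3x3(c_prev, c, rng), _Activation(activation), _MaxPool2()]
                c_prev, side = c, side // 2
            feat = side * side * c_prev
        elif backbone == "residual18":
            c_prev = 3
            for c in (8, 16, 32, 32):
                if side < 2:
                    break
                layers += [_Conv3x3(c_prev, c, rng), _Activation(activation),
                           _Residual(c, activation, rng), _MaxPool2()]
                c_prev, side = c, side // 2
            feat = side * side * c_prev
        else:
            raise ValueError(f"unknown backbone {backbone!r}")
        layers += [_Flatten(), _Dense(feat, 64, rng), _Activation(activation),
                   _Dropout(dropout, np.random.default_rng(np.random.SeedSequence([seed, 0xD0]))),
                   _Dense(64, 1, rng)]
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = x
        for layer in self.layers:
            h = layer.forward(h, train)
        return h[:, 0]

    def backward(self, dpred: np.ndarray) -> None:
        g = dpred[:, None]
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def parameters(self):
        out = []
        for layer in self.layers:
            for _name, p in layer.params():
                out.append(p)
        return out

    def gradients(self):
        out = []
        for layer in self.layers:
            out.extend(layer.grads())
        return out

    def get_weights(self):
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.parameters(), weights, strict=True):
            np.copyto(p, w)


def build_model(input_side: int, backbone: str, activation: str, dropout: float, seed: int) -> SmallConvNet:
    return SmallConvNet(input_side, backbone=backbone, activation=activation,
                        dropout=dropout, seed=seed)


class AdamW:
    """Adam with decoupled weight decay (weight decay applied directly to the
    parameters, not through the gradient moments)."""

    def __init__(self, params, lr: float, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("lr must be > 0")
        self.params = list(params)
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            if self.wd:
                p -= self.lr * self.wd * p
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
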