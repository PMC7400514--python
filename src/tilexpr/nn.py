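"""Minimal dense neural-network core: layers, backprop, Adam.

All models in this package are small multilayer perceptrons applied to
feature vectors, so a compact NumPy implementation (float64, fully seeded)
keeps the stack dependency-free and bit-reproducible on CPU.

Usage pattern: ``forward`` caches what ``backward`` needs, so call
``backward`` immediately after the matching ``forward``; gradients
accumulate across calls until ``zero_grads``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "ReLU", "Sigmoid", "Dropout", "MLP", "Adam", "build_mlp"]


class Dense:
    """Affine layer with Glorot-uniform init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.gW += self._x.T @ g
        self.gb += g.sum(axis=0)
        return g @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.gW, self.gb]


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Sigmoid:
    params: list = []
    grads: list = []

    def forward(self, x, train):
        out = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
        self._out = out
        return out

    def backward(self, g):
        return g * self._out * (1.0 - self._out)


class Dropout:
    """Inverted dropout; identity at inference."""

    params: list = []
    grads: list = []

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class MLP:
    """A stack of layers with shared forward/backward plumbing."""

    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def zero_grads(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        if len(weights) != len(self.params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(self.params, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w


_ACTIVATIONS = {"relu": ReLU, "sigmoid": Sigmoid, "linear": None}


def build_mlp(input_dim: int, hidden: tuple[int, ...], output_dim: int,
              rng: np.random.Generator, activation: str = "relu",
              dropout: float = 0.0, output_activation: str = "linear") -> MLP:
    """Dense MLP: hidden layers with the given activation (dropout between
    consecutive layers), linear or sigmoid output."""
    if activation not in _ACTIVATIONS or _ACTIVATIONS[activation] is None:
        raise ValueError(f"unsupported hidden activation {activation!r}")
    layers: list = []
    d = input_dim
    for h in hidden:
        layers.append(Dense(d, h, rng))
        layers.append(_ACTIVATIONS[activation]())
        if dropout > 0:
            layers.append(Dropout(dropout, rng))
        d = h
    layers.append(Dense(d, output_dim, rng))
    if output_activation == "sigmoid":
        layers.append(Sigmoid())
    elif output_activation != "linear":
        raise ValueError(f"unsupported output activation {output_activation!r}")
    return MLP(layers)


class Adam:
    """Adam with the standard bias correction and optional decoupled
    weight decay (applied multiplicatively, AdamW-style)."""

    def __init__(self, params: list[np.ndarray], lr: float = 3e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            if self.weight_decay and p.ndim > 1:  # decay matrices, not biases
                p *= 1.0 - self.lr * self.weight_decay
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
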