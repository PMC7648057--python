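"""Minimal dense-network machinery shared by the VAE and S-VQ-VAE.

Plain numpy: explicit forward/backward passes and an Adam optimizer.
All layers are float64 and single-threaded-deterministic; weights use a
uniform fan-in initialization U(-1/sqrt(n_in), +1/sqrt(n_in)) drawn from a
caller-provided generator so whole models are reproducible from one seed.
"""

from __future__ import annotations

import numpy as np


class Linear:
    """Affine layer x @ W + b with cached input for backprop."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        lim = 1.0 / np.sqrt(n_in)
        self.W = rng.uniform(-lim, lim, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.gW += self._x.T @ grad_out
        self.gb += grad_out.sum(axis=0)
        return grad_out @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.gW, self.gb]


class Tanh:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._out = np.tanh(x)
        return self._out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * (1.0 - self._out ** 2)

    params: list = []
    grads: list = []


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def hidden_activations(self):
        """Post-tanh activations of each hidden layer, in order."""
        return [layer._out for layer in self.layers if isinstance(layer, Tanh)]


def tanh_stack(sizes, rng) -> Sequential:
    """[Linear -> Tanh] blocks for consecutive ``sizes`` entries."""
    layers = []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        layers.append(Linear(n_in, n_out, rng))
        layers.append(Tanh())
    return Sequential(layers)


def zero_grads(grads) -> None:
    for g in grads:
        g[...] = 0.0


class Adam:
    """Adaptive-moment stochastic optimizer (beta1=0.9, beta2=0.999)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def flat_params(params) -> np.ndarray:
    return np.concatenate([p.ravel() for p in params])


def set_flat_params(params, flat: np.ndarray) -> None:
    i = 0
    for p in params:
        p[...] = flat[i:i + p.size].reshape(p.shape)
        i += p.size
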