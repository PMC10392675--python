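"""RMSprop and Adam optimizers (Keras-default smoothing constants)."""

from __future__ import annotations

import numpy as np


class Optimizer:
    def step(self, layers):
        raise NotImplementedError


class RMSprop(Optimizer):
    def __init__(self, learning_rate=1e-4, rho=0.9, epsilon=1e-7):
        self.lr = learning_rate
        self.rho = rho
        self.eps = epsilon
        self._state: dict[tuple[int, str], np.ndarray] = {}

    def step(self, layers):
        for li, layer in enumerate(layers):
            for key, p in layer.params.items():
                g = layer.grads[key]
                s = self._state.setdefault((li, key), np.zeros_like(p))
                s *= self.rho
                s += (1.0 - self.rho) * g * g
                p -= (self.lr * g / (np.sqrt(s) + self.eps)).astype(p.dtype)


class Adam(Optimizer):
    def __init__(self, learning_rate=0.01, beta_1=0.9, beta_2=0.999, epsilon=1e-7):
        self.lr = learning_rate
        self.b1 = beta_1
        self.b2 = beta_2
        self.eps = epsilon
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}
        self._t = 0

    def step(self, layers):
        self._t += 1
        lr_t = self.lr * np.sqrt(1.0 - self.b2**self._t) / (1.0 - self.b1**self._t)
        for li, layer in enumerate(layers):
            for key, p in layer.params.items():
                g = layer.grads[key]
                m = self._m.setdefault((li, key), np.zeros_like(p))
                v = self._v.setdefault((li, key), np.zeros_like(p))
                m *= self.b1
                m += (1.0 - self.b1) * g
                v *= self.b2
                v += (1.0 - self.b2) * g * g
                p -= (lr_t * m / (np.sqrt(v) + self.eps)).astype(p.dtype)


def make_optimizer(name: str, learning_rate: float) -> Optimizer:
    name = name.lower()
    if name == "rmsprop":
        return RMSprop(learning_rate=learning_rate)
    if name == "adam":
        return Adam(learning_rate=learning_rate)
    raise ValueError(f"unknown optimizer {name!r}")
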