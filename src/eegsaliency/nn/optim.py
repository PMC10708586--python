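"""Plain SGD (with optional decoupled-free L2 weight decay) and Adam."""

from __future__ import annotations

import numpy as np


class Optimizer:
    def __init__(self, network):
        self.network = network

    def step(self):
        for key, layer, name, p in self.network.parameters():
            g = layer.grads.get(name)
            if g is None:
                continue
            self._update(key, layer, name, p, g)

    def _update(self, key, layer, name, p, g):
        raise NotImplementedError


class SGD(Optimizer):
    """Stochastic gradient descent with L2 weight decay added to the gradient."""

    def __init__(self, network, lr: float = 0.001, weight_decay: float = 0.0,
                 momentum: float = 0.0):
        super().__init__(network)
        self.lr = lr
        self.weight_decay = weight_decay
        self.momentum = momentum
        self._vel: dict[str, np.ndarray] = {}

    def _update(self, key, layer, name, p, g):
        if self.weight_decay:
            g = g + self.weight_decay * p
        if self.momentum:
            v = self._vel.get(key)
            v = self.momentum * v + g if v is not None else g
            self._vel[key] = v
            g = v
        p -= self.lr * g


class Adam(Optimizer):
    def __init__(self, network, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        super().__init__(network)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        self._t = 0

    def step(self):
        self._t += 1
        super().step()

    def _update(self, key, layer, name, p, g):
        m = self._m.setdefault(key, np.zeros_like(p))
        v = self._v.setdefault(key, np.zeros_like(p))
        m += (1 - self.beta1) * (g - m)
        v += (1 - self.beta2) * (g * g - v)
        mhat = m / (1 - self.beta1**self._t)
        vhat = v / (1 - self.beta2**self._t)
        p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
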