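"""Stochastic gradient descent with classical momentum."""

from __future__ import annotations

import numpy as np


class SGD:
    """v <- mu*v + g;  p <- p - lr*v  (momentum 0 reduces to plain SGD)."""

    def __init__(self, params, lr: float, momentum: float = 0.0, weight_decay: float = 0.0):
        self.params = list(params)
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
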