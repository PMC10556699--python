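"""Stochastic gradient descent with momentum and decoupled-from-nothing L2.

Matches the conventional formulation: the weight-decay term is added to the
gradient before the momentum update (d = g + wd*p; v = mu*v + d; p -= lr*v).
"""

from __future__ import annotations

import numpy as np

__all__ = ["SGD"]


class SGD:
    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        if not self.params:
            raise ValueError("optimizer received no parameters")
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            d = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += d
            p.data = p.data - self.lr * v
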