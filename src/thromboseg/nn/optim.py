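"""Stochastic gradient descent with optional classical momentum."""

from __future__ import annotations

import numpy as np

from .tensor import Parameter

__all__ = ["SGD"]


class SGD:
    def __init__(self, params, lr: float, momentum: float = 0.0):
        self.params: list[Parameter] = list(params)
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v
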