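"""SGD with momentum and decoupled learning-rate schedules."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["SGD", "cosine_lr", "poly_lr"]


class SGD:
    """Stochastic gradient descent with classical momentum.

    Weight decay is applied as L2 regularization added to the gradient,
    the convention used by the usual deep-learning SGD implementations.
    """

    def __init__(self, params, lr: float, momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = [p for p in params if p.requires_grad]
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None or not p.requires_grad:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v


def cosine_lr(epoch: int, total_epochs: int, lr_max: float, lr_min_fraction: float = 0.01) -> float:
    """Cosine decay from ``lr_max`` to ``lr_max * lr_min_fraction``."""
    lr_min = lr_max * lr_min_fraction
    if total_epochs <= 1:
        return lr_min
    t = min(max(epoch, 0), total_epochs - 1) / (total_epochs - 1)
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + math.cos(math.pi * t))


def poly_lr(epoch: int, total_epochs: int, lr_max: float, lr_min_fraction: float = 0.01, power: float = 0.9) -> float:
    """Polynomial decay alternative with the same endpoints."""
    lr_min = lr_max * lr_min_fraction
    if total_epochs <= 1:
        return lr_min
    t = min(max(epoch, 0), total_epochs - 1) / (total_epochs - 1)
    return lr_min + (lr_max - lr_min) * (1.0 - t) ** power
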