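"""Stochastic gradient descent with momentum, weight decay and cosine
annealing of the learning rate."""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor

__all__ = ["SGD", "cosine_lr"]


def cosine_lr(t: int, total: int, lr0: float, lr_min: float = 0.0) -> float:
    """Cosine-annealed learning rate at step ``t`` of ``total``.

    ``lr_min + 0.5 * (lr0 - lr_min) * (1 + cos(pi * t / total))``.
    """
    if not 0 <= t <= total:
        raise ValueError(f"step {t} outside schedule of length {total}")
    return lr_min + 0.5 * (lr0 - lr_min) * (1.0 + math.cos(math.pi * t / total))


class SGD:
    """Classic SGD: v <- mu*v + (g + wd*w); w <- w - lr*v."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
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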