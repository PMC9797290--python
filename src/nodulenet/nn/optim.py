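"""Momentum SGD with decoupled-from-nothing classic weight decay, plus a
step learning-rate schedule — the training recipe the package defaults to
(momentum 0.9, weight decay 5e-4, initial LR 1e-3 with step decay)."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .tensor import Parameter

__all__ = ["SGD", "StepLR"]


class SGD:
    """Stochastic gradient descent with momentum and L2 weight decay.

    v <- momentum * v + grad + weight_decay * w ;  w <- w - lr * v
    """

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 1e-3,
        momentum: float = 0.9,
        weight_decay: float = 5e-4,
        clip_norm: float | None = None,
    ) -> None:
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        scale = 1.0
        if self.clip_norm is not None:
            total = np.sqrt(
                sum(float((p.grad**2).sum()) for p in self.params if p.grad is not None)
            )
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = scale * p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class StepLR:
    """Multiply the optimiser LR by ``gamma`` every ``step_size`` steps."""

    def __init__(self, optimizer: SGD, step_size: int, gamma: float = 0.1) -> None:
        self.optimizer = optimizer
        self.step_size = step_size
        self.gamma = gamma
        self._count = 0

    def step(self) -> None:
        self._count += 1
        if self._count % self.step_size == 0:
            self.optimizer.lr *= self.gamma
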