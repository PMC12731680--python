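"""AdamW optimizer with a cosine-annealing warm-restarts schedule."""

from __future__ import annotations

import math

import numpy as np

from ..errors import ParameterError
from .layers import Parameter


class AdamW:
    """Adam with decoupled L2 weight decay."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        if lr <= 0:
            raise ParameterError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= self.lr * (update + self.weight_decay * p.data)


class CosineAnnealingWarmRestarts:
    """Cosine decay from the base lr to ~0, restarting with growing period.

    Period of the first cycle is ``t0`` epochs, multiplied by ``t_mult``
    after each restart.
    """

    def __init__(self, optimizer: AdamW, t0: int = 10, t_mult: int = 2,
                 eta_min: float = 0.0):
        if t0 < 1:
            raise ParameterError("t0 must be >= 1")
        self.optimizer = optimizer
        self.base_lr = optimizer.lr
        self.t0 = t0
        self.t_mult = t_mult
        self.eta_min = eta_min
        self._cycle_len = t0
        self._cycle_pos = 0

    def lr_at(self) -> float:
        cos = 0.5 * (1.0 + math.cos(math.pi * self._cycle_pos / self._cycle_len))
        return self.eta_min + (self.base_lr - self.eta_min) * cos

    def step_epoch(self) -> float:
        """Advance one epoch and set the optimizer lr; returns the new lr."""
        self._cycle_pos += 1
        if self._cycle_pos >= self._cycle_len:
            self._cycle_pos = 0
            self._cycle_len *= self.t_mult
        lr = self.lr_at()
        self.optimizer.lr = lr
        return lr
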