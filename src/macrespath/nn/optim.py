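"""Optimisers and learning-rate schedules."""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class SGD:
    def __init__(self, params: list[Tensor], lr: float = 1e-2, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.buf = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, b in zip(self.params, self.buf):
            if p.grad is None:
                continue
            b *= self.momentum
            b += p.grad
            p.data -= self.lr * b

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def cosine_annealing_lr(step: int, base_lr: float, t_max: int,
                        eta_min: float = 0.0) -> float:
    """Cosine-annealed learning rate with warm restarts every ``t_max`` steps.

    eta_min + (base_lr - eta_min) * (1 + cos(pi * phase / t_max)) / 2, where
    the phase runs 0..t_max within each period: the rate starts at
    ``base_lr`` (step 0), reaches ``eta_min`` exactly at step ``t_max``, and
    the next step resets toward ``base_lr`` to start a new decay round.
    """
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    if step < 0:
        raise ValueError("step must be >= 0")
    phase = 0 if step == 0 else (step - 1) % t_max + 1
    return eta_min + 0.5 * (base_lr - eta_min) * (1.0 + math.cos(math.pi * phase / t_max))
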