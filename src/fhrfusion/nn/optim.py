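"""Adam optimizer and cosine-annealing learning-rate schedule."""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .autograd import Tensor

__all__ = ["Adam", "cosine_annealing_lr"]


class Adam:
    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 2.5e-4,
        betas=(0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def cosine_annealing_lr(
    epoch: int,
    initial_lr: float = 2.5e-4,
    period: int = 30,
    restart_decay: float = 0.8,
) -> float:
    """Cosine annealing with warm restarts every ``period`` epochs.

    At each restart the peak learning rate is multiplied by
    ``restart_decay``; within a cycle the rate follows a half cosine from
    the cycle peak down to 0.
    """
    cycle, within = divmod(epoch, period)
    peak = initial_lr * restart_decay**cycle
    return peak * 0.5 * (1.0 + math.cos(math.pi * within / period))
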