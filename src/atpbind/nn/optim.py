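"""Adam optimiser with global-norm gradient clipping and cosine annealing."""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor

__all__ = ["Adam", "cosine_annealing"]


def cosine_annealing(lr_init: float, lr_final: float, epoch: int, max_epochs: int) -> float:
    """Learning rate at ``epoch`` on a half-cosine from lr_init to lr_final."""
    if max_epochs <= 1:
        return lr_final
    frac = min(max(epoch / (max_epochs - 1), 0.0), 1.0)
    return lr_final + 0.5 * (lr_init - lr_final) * (1.0 + math.cos(math.pi * frac))


class Adam:
    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        clipnorm: float | None = None,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clipnorm = clipnorm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data) for p in self.params]
        if self.clipnorm is not None:
            total = math.sqrt(sum(float((g**2).sum()) for g in grads))
            if total > self.clipnorm and total > 0.0:
                scale = self.clipnorm / total
                grads = [g * scale for g in grads]
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g**2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
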