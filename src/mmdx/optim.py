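"""AdamW optimizer and cosine-annealing schedule with warm restarts."""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor

__all__ = ["AdamW", "CosineWarmRestarts"]


class AdamW:
    """Decoupled weight decay Adam.

    Weight decay is applied directly to the parameters (not through the
    gradient), scaled by the current learning rate.  Parameters whose name
    ends in ``bias`` or contains ``norm`` are exempt from decay, matching the
    regularization scope used by the training loss.
    """

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    @staticmethod
    def decays(name: str) -> bool:
        return not (name.endswith("bias") or "norm" in name)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for name, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            m = self._m[name]
            v = self._v[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and self.decays(name):
                update = update + self.weight_decay * p.data
            p.data -= self.lr * update


class CosineWarmRestarts:
    """Cosine annealing with warm restarts (SGDR schedule).

    The learning rate decays from ``lr_max`` to ``lr_min`` along a half cosine
    over ``first_restart`` epochs, then restarts with the period multiplied by
    ``period_multiplier`` (defaults: restart after 64 epochs, period doubling).
    """

    def __init__(self, lr_max: float, first_restart: int = 64,
                 period_multiplier: int = 2, lr_min: float = 0.0):
        if first_restart < 1:
            raise ValueError("first_restart must be >= 1")
        self.lr_max = lr_max
        self.lr_min = lr_min
        self.t0 = first_restart
        self.mult = period_multiplier

    def lr_at(self, epoch: int) -> float:
        """Learning rate for a zero-based epoch index."""
        t, period = epoch, self.t0
        while t >= period:
            t -= period
            period *= self.mult
        frac = t / period
        return self.lr_min + 0.5 * (self.lr_max - self.lr_min) * (1 + math.cos(math.pi * frac))
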