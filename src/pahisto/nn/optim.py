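"""Adam optimizer and the two-phase (constant, then linear-decay) LR schedule."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "linear_decay_lr"]


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def linear_decay_lr(epoch: int, base_lr: float, constant_epochs: int,
                    total_epochs: int) -> float:
    """Constant `base_lr` for `constant_epochs`, then linear decay to exactly 0
    at the final epoch (epoch index is 0-based)."""
    if epoch < constant_epochs:
        return base_lr
    decay_span = total_epochs - constant_epochs
    remaining = total_epochs - 1 - epoch
    if decay_span <= 1:
        return 0.0
    return base_lr * max(remaining, 0) / (decay_span - 1) if decay_span > 1 else 0.0
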