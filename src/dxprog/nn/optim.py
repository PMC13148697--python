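"""Adam optimizer and cosine-annealing learning-rate schedule."""

from __future__ import annotations

import math

import numpy as np


def cosine_lr(base_lr: float, lr_min: float, epoch: int, total_epochs: int) -> float:
    """Cosine annealing from base_lr (epoch 0) to lr_min (last epoch)."""
    if total_epochs <= 1:
        return base_lr
    t = epoch / (total_epochs - 1)
    return lr_min + 0.5 * (base_lr - lr_min) * (1.0 + math.cos(math.pi * t))


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for key, g in grads.items():
            m = self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            v = self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            self.params[key] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
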