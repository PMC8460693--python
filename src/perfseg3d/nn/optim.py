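"""Adam optimizer over (parameter, gradient) array pairs."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    def __init__(self, param_items, lr: float = 2e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.items = list(param_items)  # (value, grad) array pairs, updated in place
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(v) for v, _ in self.items]
        self.v = [np.zeros_like(v) for v, _ in self.items]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for (val, grad), m, v in zip(self.items, self.m, self.v):
            m *= b1
            m += (1 - b1) * grad
            v *= b2
            v += (1 - b2) * grad * grad
            val -= (self.lr / bc1) * m / (np.sqrt(v / bc2) + self.eps)
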