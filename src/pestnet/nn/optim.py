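"""AdamW optimizer with decoupled weight decay, plus a warm-up schedule."""

from __future__ import annotations

import numpy as np

from .layers import Parameter

__all__ = ["AdamW", "warmup_lr"]


class AdamW:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 5e-4):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self._v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            # decoupled decay, applied to the raw weights
            p.data -= (self.lr * (update + self.weight_decay * p.data)).astype(np.float32)


def warmup_lr(epoch: int, base_lr: float, warmup_epochs: int) -> float:
    """Linear warm-up from base_lr/100 to base_lr over ``warmup_epochs``."""
    if warmup_epochs <= 0 or epoch >= warmup_epochs:
        return base_lr
    lo = base_lr / 100.0
    return lo + (base_lr - lo) * epoch / warmup_epochs
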