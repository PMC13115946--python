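"""Generalized p-norm pooling with a learnable sharpness exponent.

``GPP(x) = ((1/HW) sum x^p)^(1/p)`` over each channel's spatial locations;
p = 1 recovers global average pooling and p -> inf approaches max pooling.
Activations are clamped to >= 1e-6 before exponentiation (the head follows
a rectified feature map, and fractional powers of negatives are undefined).
"""

from __future__ import annotations

import numpy as np

from .nn import Module, Parameter, Tensor

__all__ = ["GPP", "gpp_pool", "effective_p", "P_MIN", "CLAMP_EPS"]

P_MIN = 0.5
CLAMP_EPS = 1e-6


def effective_p(raw: float) -> float:
    """Constrain the raw learnable scalar to the valid range: max(raw, 0.5)."""
    raw = float(raw)
    if not np.isfinite(raw):
        raise ValueError(f"pooling exponent is not finite: {raw}")
    return max(raw, P_MIN)


def gpp_pool(f: np.ndarray, p: float) -> np.ndarray:
    """Reference numpy pooling of a (C, H, W) map to a length-C vector."""
    p = effective_p(p)
    f = np.asarray(f, dtype=np.float64)
    if f.ndim != 3:
        raise ValueError(f"expected a (C, H, W) feature map, got shape {f.shape}")
    x = np.maximum(f, CLAMP_EPS)
    return (x ** p).mean(axis=(1, 2)) ** (1.0 / p)


class GPP(Module):
    """Pooling head; a single shared exponent by default, per-channel optional."""

    def __init__(self, channels: int | None = None, p_init: float = 3.0,
                 per_channel: bool = False):
        super().__init__()
        if per_channel and channels is None:
            raise ValueError("per_channel pooling requires a channel count")
        shape = (channels,) if per_channel else (1,)
        self.per_channel = per_channel
        self.raw_p = Parameter(np.full(shape, p_init, dtype=np.float32))

    @property
    def p(self) -> np.ndarray:
        return np.maximum(self.raw_p.data, P_MIN)

    def forward(self, f: Tensor) -> Tensor:
        """(N, C, H, W) -> (N, C)."""
        if not np.isfinite(self.raw_p.data).all():
            raise ValueError("pooling exponent became non-finite")
        p = self.raw_p.clip_min(P_MIN)
        if self.per_channel:
            p = p.reshape(1, -1, 1, 1)
        x = f.clip_min(CLAMP_EPS)
        # x^p with learnable p, via exp(p * log x); x >= 1e-6 after the clamp
        powered = (x.log() * p).exp()
        pooled = powered.mean(axis=(2, 3))
        p_flat = p.reshape(1, -1) if self.per_channel else p
        return (pooled.log() * (p_flat ** -1.0)).exp()
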