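"""Boundary-aware channel-spatial attention.

The channel gate is a logistic transform of first/second-order channel
statistics (spatial mean and standard deviation, concatenated and mapped
2C->C by a learnable 1x1 conv).  The spatial gate runs fixed, non-trainable
Sobel kernels depthwise over the feature map, sums the horizontal and
vertical responses and fuses them C->1 with a learnable transform of 3x3
receptive field.  Both gates modulate the input in residual multiplicative
form::

    out = f * (1 + alpha * g_c) * (1 + beta * g_s)

so ``alpha = beta = 0`` is an exact identity.

Two code paths coexist deliberately: the :class:`BCSA` module (autodiff
tensors, used in training) and the plain-numpy functional ops below, which
serve as each other's cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2d, Module, ReLU, Sequential, Tensor, concat, conv2d

__all__ = [
    "SOBEL_X", "SOBEL_Y", "ChannelStats", "EdgeResponse", "BCSA",
    "channel_stats", "channel_attention", "sobel_edges", "spatial_attention",
    "bcsa_forward", "np_conv_same",
]

SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float32)
SOBEL_Y = SOBEL_X.T.copy()


@dataclass
class ChannelStats:
    mean: np.ndarray  # shape (C,)
    std: np.ndarray   # shape (C,), population convention (divisor H*W)


@dataclass
class EdgeResponse:
    ex: np.ndarray
    ey: np.ndarray


def _chw(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=np.float64)
    if f.ndim != 3:
        raise ValueError(f"expected a (C, H, W) feature map, got shape {f.shape}")
    return f


def channel_stats(f: np.ndarray) -> ChannelStats:
    """Per-channel spatial mean and population standard deviation."""
    f = _chw(f)
    mean = f.mean(axis=(1, 2))
    std = f.std(axis=(1, 2))  # numpy default ddof=0 == divisor H*W
    return ChannelStats(mean=mean, std=std)


def channel_attention(stats: ChannelStats, weight: np.ndarray,
                      bias: np.ndarray | None = None) -> np.ndarray:
    """g_c = logistic(W_c . [mu, sigma]); weight shape (C_out, 2C)."""
    descriptor = np.concatenate([stats.mean, stats.std])
    weight = np.asarray(weight, dtype=np.float64)
    if weight.ndim != 2 or weight.shape[1] != descriptor.size:
        raise ValueError(
            f"channel transform expects shape (C_out, {descriptor.size}), "
            f"got {weight.shape}")
    z = weight @ descriptor
    if bias is not None:
        z = z + np.asarray(bias, dtype=np.float64)
    return 1.0 / (1.0 + np.exp(-z))


def np_conv_same(x: np.ndarray, weight: np.ndarray,
                 bias: np.ndarray | None = None) -> np.ndarray:
    """Zero-padded same cross-correlation: (C,H,W) x (O,C,kh,kw) -> (O,H,W)."""
    x = np.asarray(x, dtype=np.float64)
    weight = np.asarray(weight, dtype=np.float64)
    o, c, kh, kw = weight.shape
    if x.shape[0] != c:
        raise ValueError(f"conv expects {c} input channels, got {x.shape[0]}")
    xp = np.pad(x, ((0, 0), (kh // 2, kh // 2), (kw // 2, kw // 2)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    out = np.einsum("chwij,ocij->ohw", win, weight)
    if bias is not None:
        out = out + np.asarray(bias, dtype=np.float64)[:, None, None]
    return out


def sobel_edges(f: np.ndarray) -> EdgeResponse:
    """Fixed depthwise Sobel responses with zero same-padding.

    Edge pixels carry padding artifacts; assertions belong on the interior.
    """
    f = _chw(f)
    ex = np.stack([np_conv_same(ch[None], SOBEL_X[None, None])[0] for ch in f])
    ey = np.stack([np_conv_same(ch[None], SOBEL_Y[None, None])[0] for ch in f])
    return EdgeResponse(ex=ex, ey=ey)


def spatial_attention(edges: EdgeResponse, weights: list[tuple[np.ndarray, np.ndarray | None]],
                      ) -> np.ndarray:
    """g_s = logistic(W_s . (E_x + E_y)) with W_s given as conv stages.

    ``weights`` is a list of (kernel, bias) pairs applied in order with a
    ReLU between stages; the final stage must map to one channel.
    """
    x = edges.ex + edges.ey
    for i, (w, b) in enumerate(weights):
        x = np_conv_same(x, w, b)
        if i < len(weights) - 1:
            x = np.maximum(x, 0.0)
    if x.shape[0] != 1:
        raise ValueError(f"spatial transform must end in one channel, got {x.shape[0]}")
    return 1.0 / (1.0 + np.exp(-x))


class BCSA(Module):
    """Learnable attention module (autodiff path).

    ``spatial_hidden=None`` uses a single 3x3 conv C->1 for the spatial
    gate; an integer inserts a 3x3 conv C->hidden + ReLU + 1x1 conv
    hidden->1 (the default model uses per-stage hidden widths chosen to
    keep the full architecture at its 35.65 M parameter budget).
    """

    def __init__(self, channels: int, alpha: float = 1.0, beta: float = 1.0,
                 spatial_hidden: int | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if alpha < 0 or beta < 0 or not np.isfinite([alpha, beta]).all():
            raise ValueError("alpha and beta must be finite and non-negative")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.channels = channels
        self.alpha = float(alpha)
        self.beta = float(beta)
        self.wc = Conv2d(2 * channels, channels, 1, bias=True, rng=rng)
        if spatial_hidden is None:
            self.ws = Sequential(Conv2d(channels, 1, 3, padding=1, bias=True, rng=rng))
        else:
            self.ws = Sequential(
                Conv2d(channels, spatial_hidden, 3, padding=1, bias=True, rng=rng),
                ReLU(),
                Conv2d(spatial_hidden, 1, 1, bias=True, rng=rng),
            )
        self._sobel_x = Tensor(SOBEL_X[None, None])
        self._sobel_y = Tensor(SOBEL_Y[None, None])

    # -- tensor-path pieces --------------------------------------------------

    def channel_gate(self, f: Tensor) -> Tensor:
        mu = f.mean(axis=(2, 3), keepdims=True)
        centered = f - mu
        var = (centered * centered).mean(axis=(2, 3), keepdims=True)
        sigma = var.sqrt()
        descriptor = concat([mu, sigma], axis=1)
        return self.wc(descriptor).sigmoid()

    def edge_responses(self, f: Tensor) -> tuple[Tensor, Tensor]:
        n, c, h, w = f.shape
        flat = f.reshape(n * c, 1, h, w)
        ex = conv2d(flat, self._sobel_x, padding=1).reshape(n, c, h, w)
        ey = conv2d(flat, self._sobel_y, padding=1).reshape(n, c, h, w)
        return ex, ey

    def spatial_gate(self, f: Tensor) -> Tensor:
        ex, ey = self.edge_responses(f)
        return self.ws(ex + ey).sigmoid()

    def forward(self, f: Tensor) -> Tensor:
        g_c = self.channel_gate(f)
        g_s = self.spatial_gate(f)
        return f * (1.0 + self.alpha * g_c) * (1.0 + self.beta * g_s)

    # -- numpy export for the functional cross-check -------------------------

    def spatial_weights(self) -> list[tuple[np.ndarray, np.ndarray | None]]:
        pairs = []
        for layer in self.ws.layers:
            if isinstance(layer, Conv2d):
                pairs.append((layer.weight.data.copy(),
                              None if layer.bias is None else layer.bias.data.copy()))
        return pairs


def bcsa_forward(f: np.ndarray, module: BCSA) -> np.ndarray:
    """Plain-numpy composition of the attention sub-operations.

    Independent of the autodiff path; used to cross-check
    :meth:`BCSA.forward` on a single (C, H, W) map.
    """
    f = _chw(f)
    stats = channel_stats(f)
    wc_w = module.wc.weight.data.reshape(module.channels, 2 * module.channels)
    wc_b = module.wc.bias.data if module.wc.bias is not None else None
    g_c = channel_attention(stats, wc_w, wc_b)
    g_s = spatial_attention(sobel_edges(f), module.spatial_weights())
    return f * (1.0 + module.alpha * g_c[:, None, None]) * (1.0 + module.beta * g_s)
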