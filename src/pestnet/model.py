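"""Full classifier: OSA backbone + per-stage attention + GPP head.

The default configuration (224x224 input, four attention blocks, a single
shared pooling exponent and a 168-class training head) totals 35.65 M
trainable parameters.  The spatial-gate hidden widths below are the
calibrated degree of freedom that pins the budget to that figure.
"""

from __future__ import annotations

import numpy as np

from .backbone import BackboneConfig, OSABackbone, reduced_config, vovnet57_config
from .bcsa import BCSA
from .gpp import GPP
from .nn import Linear, Module, Tensor

__all__ = ["PestNet", "build_model", "DEFAULT_SPATIAL_HIDDEN"]

#: per-stage spatial-gate hidden widths of the default model
DEFAULT_SPATIAL_HIDDEN = (17, 33, 49, 66)


class PestNet(Module):
    def __init__(self, n_classes: int, backbone_cfg: BackboneConfig | None = None,
                 alpha: float = 1.0, beta: float = 1.0,
                 spatial_hidden: tuple[int | None, ...] | None = DEFAULT_SPATIAL_HIDDEN,
                 use_bcsa: bool = True, p_init: float = 3.0,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        cfg = backbone_cfg if backbone_cfg is not None else vovnet57_config()
        self.n_classes = n_classes
        attention = None
        if use_bcsa:
            hidden = spatial_hidden if spatial_hidden is not None \
                else (None,) * len(cfg.stage_out)
            attention = [
                BCSA(c, alpha=alpha, beta=beta, spatial_hidden=h, rng=rng)
                for c, h in zip(cfg.stage_out, hidden)
            ]
        self.backbone = OSABackbone(cfg, attention=attention, rng=rng)
        self.pool = GPP(channels=cfg.terminal_channels)
        self.head = Linear(cfg.terminal_channels, n_classes, rng=rng)

    def forward(self, image: Tensor) -> Tensor:
        """(N, 3, H, W) -> logits (N, n_classes)."""
        features = self.backbone(image)[-1]
        return self.head(self.pool(features))


def build_model(n_classes: int, arch: str = "vovnet57",
                alpha: float = 1.0, beta: float = 1.0,
                seed: int = 0, use_bcsa: bool = True) -> PestNet:
    rng = np.random.default_rng(seed)
    if arch == "vovnet57":
        return PestNet(n_classes, vovnet57_config(), alpha=alpha, beta=beta,
                       spatial_hidden=DEFAULT_SPATIAL_HIDDEN,
                       use_bcsa=use_bcsa, rng=rng)
    if arch == "reduced":
        return PestNet(n_classes, reduced_config(), alpha=alpha, beta=beta,
                       spatial_hidden=None, use_bcsa=use_bcsa, rng=rng)
    raise ValueError(f"unknown architecture: {arch!r}")
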