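"""One-shot-aggregation (OSA) backbone.

Each OSA block chains ``n_layers`` 3x3 conv-BN-ReLU layers, concatenates
all intermediate outputs once at the block end and projects the concat to
the stage width with a 1x1 conv.  The default configuration follows the
57-layer staging (stem 64/64/128; per-layer widths 128/160/192/224; stage
outputs 256/512/768/1024; 1/1/4/3 blocks per stage), terminating in a
1024-channel 7x7 map for a 3x224x224 input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    BatchNorm2d, Conv2d, Module, ReLU, Sequential, Tensor, concat, maxpool2x2,
)

__all__ = [
    "OSAConfig", "BackboneConfig", "OSABlock", "OSABackbone",
    "vovnet57_config", "reduced_config", "count_parameters",
    "param_millions", "load_pretrained", "LoadReport",
]


@dataclass(frozen=True)
class OSAConfig:
    in_channels: int
    per_layer_channels: int
    out_channels: int
    n_layers: int = 5
    kernel_size: int = 3

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")

    @property
    def concat_channels(self) -> int:
        return self.n_layers * self.per_layer_channels


@dataclass(frozen=True)
class BackboneConfig:
    stem_channels: tuple[int, int, int] = (64, 64, 128)
    stage_per_layer: tuple[int, ...] = (128, 160, 192, 224)
    stage_out: tuple[int, ...] = (256, 512, 768, 1024)
    blocks_per_stage: tuple[int, ...] = (1, 1, 4, 3)
    osa_layers: int = 5
    input_size: int = 224

    @property
    def terminal_channels(self) -> int:
        return self.stage_out[-1]


def vovnet57_config() -> BackboneConfig:
    return BackboneConfig()


def reduced_config() -> BackboneConfig:
    """Small variant for CPU-scale smoke training (64x64 inputs)."""
    return BackboneConfig(
        stem_channels=(16, 16, 32),
        stage_per_layer=(16, 20, 24, 28),
        stage_out=(32, 48, 64, 96),
        blocks_per_stage=(1, 1, 1, 1),
        osa_layers=3,
        input_size=64,
    )


def _conv_bn_relu(inc: int, outc: int, k: int, stride: int,
                  rng: np.random.Generator) -> Sequential:
    pad = k // 2
    return Sequential(
        Conv2d(inc, outc, k, stride=stride, padding=pad, bias=False, rng=rng),
        BatchNorm2d(outc),
        ReLU(),
    )


class OSABlock(Module):
    def __init__(self, cfg: OSAConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cfg = cfg
        inc = cfg.in_channels
        layers = []
        for _ in range(cfg.n_layers):
            layers.append(_conv_bn_relu(inc, cfg.per_layer_channels,
                                        cfg.kernel_size, 1, rng))
            inc = cfg.per_layer_channels
        self.conv_layers = layers
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)
        self.project = _conv_bn_relu(cfg.concat_channels, cfg.out_channels, 1, 1, rng)

    def forward(self, f: Tensor) -> Tensor:
        if f.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"OSA block expects {self.cfg.in_channels} input channels, "
                f"got {f.shape[1]}")
        outputs = []
        y = f
        for layer in self.conv_layers:
            y = layer(y)
            outputs.append(y)
        # one-shot aggregation: concat the intermediate maps only
        return self.project(concat(outputs, axis=1))


class OSABackbone(Module):
    """Stem + four OSA stages, optionally with an attention module per stage.

    ``forward`` returns the ordered list of stage outputs (after attention
    when attached); the final entry is the terminal feature map.
    """

    def __init__(self, cfg: BackboneConfig | None = None,
                 attention: list[Module] | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg = cfg if cfg is not None else vovnet57_config()
        rng = rng if rng is not None else np.random.default_rng(0)
        c0, c1, c2 = cfg.stem_channels
        self.stem = Sequential(
            _conv_bn_relu(3, c0, 3, 2, rng),
            _conv_bn_relu(c0, c1, 3, 1, rng),
            _conv_bn_relu(c1, c2, 3, 2, rng),
        )
        n_stages = len(cfg.stage_out)
        stages = []
        inc = c2
        for s in range(n_stages):
            blocks = []
            for _ in range(cfg.blocks_per_stage[s]):
                blocks.append(OSABlock(OSAConfig(
                    in_channels=inc,
                    per_layer_channels=cfg.stage_per_layer[s],
                    out_channels=cfg.stage_out[s],
                    n_layers=cfg.osa_layers), rng))
                inc = cfg.stage_out[s]
            stages.append(Sequential(*blocks))
        self.stages = stages
        for i, stage in enumerate(stages):
            setattr(self, f"stage{i}", stage)
        if attention is not None and len(attention) != n_stages:
            raise ValueError(f"need one attention module per stage "
                             f"({n_stages}), got {len(attention)}")
        self.attention = attention
        if attention is not None:
            for i, mod in enumerate(attention):
                setattr(self, f"attn{i}", mod)

    def forward(self, image: Tensor) -> list[Tensor]:
        if image.ndim == 3:
            image = image.reshape(1, *image.shape)
        if image.shape[1] != 3:
            raise ValueError(f"expected a 3-channel image, got {image.shape[1]}")
        x = self.stem(image)
        outputs: list[Tensor] = []
        for i, stage in enumerate(self.stages):
            if i > 0:
                x = maxpool2x2(x)
            x = stage(x)
            if self.attention is not None:
                x = self.attention[i](x)
            outputs.append(x)
        return outputs


def count_parameters(model: Module) -> int:
    """Total number of trainable scalar parameters."""
    return sum(int(np.prod(p.shape)) for p in model.parameters())


def param_millions(model: Module) -> float:
    return round(count_parameters(model) / 1e6, 2)


@dataclass
class LoadReport:
    loaded: list[str] = field(default_factory=list)
    missing: list[str] = field(default_factory=list)
    unexpected: list[str] = field(default_factory=list)


def load_pretrained(weights: "str | dict[str, np.ndarray]",
                    model: Module) -> LoadReport:
    """Load a key->array archive into ``model`` by name.

    Keys present in the archive but absent from the model are reported as
    unexpected; model keys absent from the archive stay at their fresh
    initialization and are reported as missing.  A shape mismatch raises.
    """
    if isinstance(weights, (str, bytes)) or hasattr(weights, "__fspath__"):
        with np.load(weights) as archive:
            state = {k: archive[k] for k in archive.files}
    else:
        state = dict(weights)
    loaded, missing, unexpected = model.load_state_dict(state, strict=False)
    return LoadReport(loaded=loaded, missing=missing, unexpected=unexpected)
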