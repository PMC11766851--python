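"""The full segmentation model: encoder, shuffle + CAT blocks, decoder, head.

Wiring (default embed dim 48): the transformer encoder produces feature maps
at six levels with channels (48, 48, 96, 192, 384, 768); the five
transformer-derived maps (levels 1-5) are channel-shuffled; all six maps
pass through CAT encoding blocks; five residual decoder blocks walk the
ladder back to full resolution; a 1x1x1 sigmoid head emits the three
overlapping subregion probabilities (WT, TC, ET).

Ablation switches (`shuffle.enabled`, `attention.enabled`) reproduce the
four study variants — full model, no attention, no shuffle, neither — from
one configuration each; shuffling is parameter-free, so only the attention
switch changes the parameter count.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .blocks import AttentionConfig, CATBlock, ShuffleConfig, channel_shuffle
from .decoder import DecoderConfig, ResidualDecoderBlock, SegmentationHead
from .encoder import EncoderConfig, SwinEncoder
from .nn import Module, ModuleList, Tensor, no_grad

__all__ = ["ModelConfig", "ECATBraTS", "attention_parameter_count"]


@dataclass
class ModelConfig:
    """All architecture hyperparameters in one place (YAML-serialisable)."""

    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    shuffle: ShuffleConfig = field(default_factory=ShuffleConfig)
    attention: AttentionConfig = field(default_factory=AttentionConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    out_channels: int = 3
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key, sub in (("encoder", EncoderConfig), ("shuffle", ShuffleConfig),
                         ("attention", AttentionConfig), ("decoder", DecoderConfig)):
            if key in d and isinstance(d[key], dict):
                sub_d = dict(d[key])
                for k, v in sub_d.items():
                    if isinstance(v, list):
                        sub_d[k] = tuple(v)
                d[key] = sub(**sub_d)
        return cls(**d)

    def ladder(self) -> tuple[int, ...]:
        """Channel widths at levels 0..5."""
        return tuple(self.encoder.channels(level) for level in range(6))


def tiny_model_config(seed: int = 0) -> ModelConfig:
    """A CPU-scale configuration (embed dim 8, small windows) used by the
    documentation examples and the overfitting demonstration."""
    return ModelConfig(
        encoder=EncoderConfig(embed_dim=8, num_heads=(2, 2, 2, 2),
                              window_size=(4, 4, 4)),
        seed=seed,
    )


class ECATBraTS(Module):
    """Channel-attention transformer for 3D brain-tumour segmentation."""

    def __init__(self, cfg: ModelConfig | None = None):
        super().__init__()
        self.cfg = cfg = cfg if cfg is not None else ModelConfig()
        rng = np.random.default_rng(cfg.seed)
        ladder = cfg.ladder()
        for c in ladder[1:]:
            if cfg.shuffle.enabled:
                cfg.shuffle.validate_channels(c)
        self.encoder = SwinEncoder(cfg.encoder, rng)
        self.cat_blocks = ModuleList([
            CATBlock(c, c, cfg.attention, rng) for c in ladder
        ])
        self.decoder_blocks = ModuleList([
            ResidualDecoderBlock(ladder[level], ladder[level - 1],
                                 cfg.decoder, rng)
            for level in range(5, 0, -1)
        ])
        self.head = SegmentationHead(ladder[0], rng,
                                     out_channels=cfg.out_channels)

    # structural constants, as counted in the architecture description
    @property
    def num_cat_blocks(self) -> int:
        return len(self.cat_blocks)

    @property
    def num_shuffle_blocks(self) -> int:
        """Shuffling applies to the five transformer-derived maps (levels 1-5)."""
        return 5 if self.cfg.shuffle.enabled else 0

    @property
    def num_decoder_blocks(self) -> int:
        return len(self.decoder_blocks)

    def forward(self, x: Tensor) -> Tensor:
        """(N, 4, D, H, W) volume -> (N, 3, D, H, W) subregion probabilities."""
        features = self.encoder(x)
        encoded = []
        for level, (fmap, block) in enumerate(zip(features, self.cat_blocks)):
            if level >= 1 and self.cfg.shuffle.enabled:
                fmap = channel_shuffle(fmap, self.cfg.shuffle.groups)
            encoded.append(block(fmap))
        y = encoded[5]
        for i, dec in enumerate(self.decoder_blocks):
            y = dec(y, encoded[4 - i])
        return self.head(y)

    def predict(self, volume: np.ndarray) -> np.ndarray:
        """Inference helper: numpy (4, D, H, W) -> probabilities (3, D, H, W)."""
        self.eval()
        with no_grad():
            probs = self.forward(Tensor(volume[None].astype(np.float32)))
        return probs.data[0]


def attention_parameter_count(cfg: ModelConfig) -> int:
    """Closed-form count of the channel-attention FC parameters over all six
    CAT blocks: per block, C*(C/r) + C/r (FC1) + (C/r)*C + C (FC2)."""
    r = cfg.attention.reduction
    total = 0
    for c in cfg.ladder():
        h = c // r
        total += c * h + h + h * c + c
    return total
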