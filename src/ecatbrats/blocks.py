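"""Channel shuffling and channel-attention (CAT) encoding blocks.

Channel shuffling is a parameter-free regulariser: the C channels of a
feature map are reshaped into G groups, the group and within-group axes are
transposed, and the result is flattened back — so information mixes across
channel groups at no cost.  The CAT encoding block is the model's encoding
unit: a 3x3x3 convolution (stride 1, padding 1, so the spatial extent is
preserved), 3D batch normalisation, a squeeze-and-excitation style channel
attention module (global average pooling, a bottlenecked pair of fully
connected layers, sigmoid gating) and a LeakyReLU output activation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import BatchNorm3d, Conv3d, Linear, Module, Tensor

__all__ = ["ShuffleConfig", "AttentionConfig", "channel_shuffle",
           "global_avg_pool", "ChannelAttention", "CATBlock"]

LEAKY_SLOPE = 0.01


@dataclass
class ShuffleConfig:
    groups: int = 4
    enabled: bool = True

    def __post_init__(self):
        if self.groups < 1:
            raise ValueError("shuffle groups must be >= 1")

    def validate_channels(self, channels: int) -> None:
        if channels % self.groups:
            raise ValueError(
                f"shuffle groups {self.groups} do not divide {channels} channels")


@dataclass
class AttentionConfig:
    reduction: int = 4
    enabled: bool = True

    def __post_init__(self):
        if self.reduction < 1:
            raise ValueError("attention reduction must be >= 1")

    def validate_channels(self, channels: int) -> None:
        if channels % self.reduction:
            raise ValueError(
                f"attention reduction {self.reduction} does not divide "
                f"{channels} channels")


def channel_shuffle(x: Tensor, groups: int) -> Tensor:
    """Permute channels by the reshape-(G, C/G)-transpose-flatten rule.

    Output channel j*G + i holds input channel i*(C/G) + j; spatial content
    is untouched and the operation has no parameters.  G must divide C (this
    is validated at model build time by :meth:`ShuffleConfig.validate_channels`).
    """
    n, c = x.shape[0], x.shape[1]
    if c % groups:
        raise ValueError(f"channel count {c} not divisible by groups {groups}")
    if groups == 1:
        return x
    spatial = x.shape[2:]
    x = x.reshape(n, groups, c // groups, *spatial)
    x = x.transpose(0, 2, 1, *range(3, 3 + len(spatial)))
    return x.reshape(n, c, *spatial)


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean of each channel over all spatial positions: (N, C, D, H, W) -> (N, C)."""
    return x.mean(axis=(2, 3, 4))


class ChannelAttention(Module):
    """Squeeze-and-excitation channel gating.

    Gates g = sigmoid(FC2(LeakyReLU(FC1(GAP(x))))) with FC1: C -> C/r and
    FC2: C/r -> C rescale each channel; ``enabled=False`` makes the module
    the identity (the ablation switch).
    """

    def __init__(self, channels: int, cfg: AttentionConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        if cfg.enabled:  # the ablated variant carries no FC parameters
            cfg.validate_channels(channels)
            self.fc1 = Linear(channels, channels // cfg.reduction, rng)
            self.fc2 = Linear(channels // cfg.reduction, channels, rng)

    def gates(self, x: Tensor) -> Tensor:
        m = global_avg_pool(x)
        return self.fc2(self.fc1(m).leaky_relu(LEAKY_SLOPE)).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        if not self.cfg.enabled:
            return x
        g = self.gates(x)
        n, c = g.shape
        return x * g.reshape(n, c, 1, 1, 1)


class CATBlock(Module):
    """Conv3x3x3 (stride 1, pad 1) -> BatchNorm3d -> channel attention ->
    LeakyReLU; spatial extent preserved, channels become ``out_channels``."""

    def __init__(self, in_channels: int, out_channels: int,
                 cfg: AttentionConfig, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv3d(in_channels, out_channels, 3, rng)
        self.norm = BatchNorm3d(out_channels)
        self.attention = ChannelAttention(out_channels, cfg, rng)
        self.out_channels = out_channels

    def forward(self, x: Tensor) -> Tensor:
        return self.attention(self.norm(self.conv(x))).leaky_relu(LEAKY_SLOPE)
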