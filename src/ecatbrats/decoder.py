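"""Residual decoder and segmentation head.

Five residual decoding blocks walk the encoder ladder back up: each block
upsamples the deeper map by a factor of 2 per axis, concatenates it with the
skip feature map one level shallower, and refines the result with a residual
convolution unit.  A final 1x1x1 convolution with a sigmoid produces three
independent per-voxel probabilities for the nested, overlapping subregions
(WT, TC, ET) — sigmoid rather than softmax because the targets overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import SubregionMask
from .nn import (BatchNorm3d, Conv3d, ConvTranspose3dX2, Module, Tensor,
                 concat, upsample2x_trilinear)
from .blocks import LEAKY_SLOPE

logger = logging.getLogger(__name__)

__all__ = ["DecoderConfig", "ResidualDecoderBlock", "SegmentationHead",
           "predict_mask"]


@dataclass
class DecoderConfig:
    upsample_mode: str = "transpose-conv"  # or "trilinear+conv"

    def __post_init__(self):
        if self.upsample_mode not in ("transpose-conv", "trilinear+conv"):
            raise ValueError(f"unknown upsample mode {self.upsample_mode!r}")


def _match_grid(x: Tensor, target: tuple[int, int, int]) -> Tensor:
    """Crop/zero-pad the trailing three axes to the skip grid (logged)."""
    if x.shape[2:] == tuple(target):
        return x
    logger.debug("decoder grid adjust %s -> %s", x.shape[2:], target)
    sl = [slice(None), slice(None)]
    pw = [(0, 0), (0, 0)]
    for s, t in zip(x.shape[2:], target):
        sl.append(slice(0, min(s, t)))
        pw.append((0, max(0, t - s)))
    x = x[tuple(sl)]
    if any(p != (0, 0) for p in pw):
        x = x.pad(pw)
    return x


class ResidualDecoderBlock(Module):
    """Upsample 2x, merge with the skip by concatenation, refine residually.

    The main branch is conv3-BN-LeakyReLU-conv3-BN; a 1x1x1 projection of the
    merged input provides the shortcut, and the sum passes through LeakyReLU.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 cfg: DecoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        if cfg.upsample_mode == "transpose-conv":
            self.up = ConvTranspose3dX2(in_channels, out_channels, rng)
            self.up_proj = None
        else:
            self.up = None
            self.up_proj = Conv3d(in_channels, out_channels, 1, rng)
        merged = 2 * out_channels
        self.conv1 = Conv3d(merged, out_channels, 3, rng)
        self.norm1 = BatchNorm3d(out_channels)
        self.conv2 = Conv3d(out_channels, out_channels, 3, rng)
        self.norm2 = BatchNorm3d(out_channels)
        self.shortcut = Conv3d(merged, out_channels, 1, rng)

    def forward(self, deep: Tensor, skip: Tensor) -> Tensor:
        if self.up is not None:
            up = self.up(deep)
        else:
            up = self.up_proj(upsample2x_trilinear(deep))
        up = _match_grid(up, skip.shape[2:])
        z = concat([up, skip], axis=1)
        main = self.norm2(self.conv2(
            self.norm1(self.conv1(z)).leaky_relu(LEAKY_SLOPE)))
        return (main + self.shortcut(z)).leaky_relu(LEAKY_SLOPE)


class SegmentationHead(Module):
    """1x1x1 convolution to 3 channels with sigmoid activation."""

    def __init__(self, in_channels: int, rng: np.random.Generator,
                 out_channels: int = 3):
        super().__init__()
        self.conv = Conv3d(in_channels, out_channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x).sigmoid()


def predict_mask(probabilities: np.ndarray | Tensor,
                 threshold: float = 0.5) -> SubregionMask:
    """Binarise per-channel probabilities (3, D, H, W) into a SubregionMask.

    Nesting is not enforced; a violation is surfaced via
    :meth:`SubregionMask.nesting_ok` by callers that care (QC flag).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    probs = probabilities.data if isinstance(probabilities, Tensor) else probabilities
    probs = np.asarray(probs)
    if probs.ndim == 5:
        if probs.shape[0] != 1:
            raise ValueError("pass a single case, not a batch")
        probs = probs[0]
    if probs.ndim != 4 or probs.shape[0] != 3:
        raise ValueError(f"expected (3, D, H, W) probabilities, got {probs.shape}")
    return SubregionMask((probs >= threshold).astype(np.uint8))
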