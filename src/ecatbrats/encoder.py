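"""Shifted-window (Swin) transformer encoder for 4-channel MRI volumes.

The front end splits the volume into non-overlapping 2x2x2 patches, embeds
them linearly, and runs four stages of window-based transformer blocks.
Blocks alternate between regular and half-window-shifted window partitions;
self-attention is computed inside local 3D windows with a learned relative
position bias, and a patch-merging layer between stages halves each spatial
extent while doubling the channel width.  With embed dim 48 the channel
ladder over levels 0..5 is (48, 48, 96, 192, 384, 768), level L sitting at
1/2^L of the input resolution.

Token tensors use the layout (N, D, H, W, C); feature maps returned to the
rest of the network use (N, C, D, H, W).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .nn import LayerNorm, Linear, Module, ModuleList, Parameter, Tensor, concat
from .nn.layers import Conv3d, _DTYPE

logger = logging.getLogger(__name__)

_MASK_NEG = -1e9
#: bound on chunk * heads * T^2 logits elements per attention chunk (~128 MB)
_ATTN_CHUNK_ELEMS = 2 ** 25


@dataclass
class EncoderConfig:
    """Hyperparameters of the transformer front end."""

    in_channels: int = 4
    patch_size: int = 2
    embed_dim: int = 48
    depths: tuple[int, ...] = (2, 2, 2, 2)
    num_heads: tuple[int, ...] = (3, 6, 12, 24)
    window_size: tuple[int, int, int] = (7, 7, 7)
    mlp_ratio: float = 4.0

    def __post_init__(self):
        if any(d < 1 for d in self.depths):
            raise ValueError("stage depths must be positive")
        if len(self.depths) != 4 or len(self.num_heads) != 4:
            raise ValueError("expected 4 stages of depths and heads")

    def channels(self, level: int) -> int:
        """Channel width of the feature ladder at ``level`` in 0..5."""
        return self.embed_dim * (1 if level <= 1 else 2 ** (level - 1))


def _effective_window(grid: tuple[int, ...], window: tuple[int, ...],
                      shifted: bool) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Clip the window to the token grid; suppress the shift along axes with
    a single window (shifting would only wrap the same tokens)."""
    ws, ss = [], []
    for g, w in zip(grid, window):
        w_eff = min(w, g)
        pad_to = -(-g // w_eff) * w_eff
        s_eff = w_eff // 2 if (shifted and pad_to > w_eff and w_eff > 1) else 0
        ws.append(w_eff)
        ss.append(s_eff)
    return tuple(ws), tuple(ss)


@lru_cache(maxsize=128)
def _attention_mask(grid: tuple[int, ...], window: tuple[int, ...],
                    shift: tuple[int, ...]) -> np.ndarray | None:
    """Additive (num_windows, T, T) mask for padded and shifted partitions.

    Voxels are labelled with a region id; attention between differing ids is
    blocked.  Padded voxels get unique ids so they only attend themselves
    (their outputs are cropped away afterwards).
    """
    d, h, w = grid
    pd, ph, pw = [-(-g // s) * s for g, s in zip(grid, window)]
    if (pd, ph, pw) == grid and not any(shift):
        return None
    ids = -(np.arange(pd * ph * pw, dtype=np.int64).reshape(pd, ph, pw) + 1)
    region = np.zeros((pd, ph, pw), dtype=np.int64)
    cnt = 0
    for sd in _shift_slices(pd, window[0], shift[0]):
        for sh in _shift_slices(ph, window[1], shift[1]):
            for sw in _shift_slices(pw, window[2], shift[2]):
                region[sd, sh, sw] = cnt
                cnt += 1
    ids[:d, :h, :w] = region[:d, :h, :w]
    if any(shift):
        ids = np.roll(ids, tuple(-s for s in shift), axis=(0, 1, 2))
    wd, wh, ww = window
    ids = ids.reshape(pd // wd, wd, ph // wh, wh, pw // ww, ww)
    ids = ids.transpose(0, 2, 4, 1, 3, 5).reshape(-1, wd * wh * ww)
    mask = np.where(ids[:, :, None] == ids[:, None, :], 0.0, _MASK_NEG)
    return mask.astype(_DTYPE)


def _shift_slices(size: int, window: int, shift: int):
    if shift == 0:
        return (slice(0, size),)
    return (slice(0, size - window), slice(size - window, size - shift),
            slice(size - shift, size))


@lru_cache(maxsize=32)
def _relative_index(window: tuple[int, int, int]) -> np.ndarray:
    """(T, T) index into the flattened relative-position-bias table."""
    coords = np.stack(np.meshgrid(*(np.arange(w) for w in window),
                                  indexing="ij")).reshape(3, -1)
    rel = coords[:, :, None] - coords[:, None, :]  # (3, T, T)
    rel = rel + np.array([w - 1 for w in window]).reshape(3, 1, 1)
    strides = ((2 * window[1] - 1) * (2 * window[2] - 1), 2 * window[2] - 1, 1)
    return (rel[0] * strides[0] + rel[1] * strides[1] + rel[2]).astype(np.int64)


class WindowAttention(Module):
    """Multi-head self-attention inside local 3D windows with a learned
    relative position bias."""

    def __init__(self, dim: int, num_heads: int, window: tuple[int, int, int],
                 rng: np.random.Generator):
        super().__init__()
        if dim % num_heads:
            raise ValueError(f"dim {dim} not divisible by heads {num_heads}")
        self.dim = dim
        self.num_heads = num_heads
        self.window = tuple(window)
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        table_len = int(np.prod([2 * w - 1 for w in self.window]))
        self.rel_bias_table = Parameter(
            np.zeros((table_len, num_heads), dtype=_DTYPE))
        self.store_attn = False
        self.last_attn: np.ndarray | None = None

    def forward(self, x: Tensor, window: tuple[int, int, int],
                mask: np.ndarray | None) -> Tensor:
        """``x``: windows (B, T, C) with the window index varying fastest
        within each volume; ``mask``: additive (num_windows, T, T) or None.

        Windows are processed in chunks so the (chunk, heads, T, T) logits
        stay bounded in memory at full volume resolution.
        """
        b, t, c = x.shape
        h = self.num_heads
        hd = c // h
        idx = _relative_index(window)
        bias = self.rel_bias_table[idx.ravel()].reshape(t, t, h).transpose(2, 0, 1)
        chunk = max(1, _ATTN_CHUNK_ELEMS // max(1, h * t * t))
        outs = []
        attn_chunks = [] if self.store_attn else None
        for i0 in range(0, b, chunk):
            i1 = min(b, i0 + chunk)
            xb = x[i0:i1]
            qkv = self.qkv(xb)  # (bc, T, 3C)
            qkv = qkv.reshape(i1 - i0, t, 3, h, hd).transpose(2, 0, 3, 1, 4)
            q, k, v = qkv[0], qkv[1], qkv[2]  # (bc, h, T, hd)
            logits = (q @ k.transpose(0, 1, 3, 2)) * (hd ** -0.5) + bias
            if mask is not None:
                nw = mask.shape[0]
                ids = np.arange(i0, i1) % nw
                logits = logits + mask[ids][:, None]
            attn = logits.softmax(axis=-1)
            if attn_chunks is not None:
                attn_chunks.append(attn.data.copy())
            outs.append((attn @ v).transpose(0, 2, 1, 3).reshape(i1 - i0, t, c))
        if attn_chunks is not None:
            self.last_attn = np.concatenate(attn_chunks, axis=0)
        out = outs[0] if len(outs) == 1 else concat(outs, axis=0)
        return self.proj(out)


class Mlp(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class SwinBlock(Module):
    """One transformer block: windowed attention and MLP, both residual and
    layer-normalised; ``shifted`` selects the half-window-shifted partition."""

    def __init__(self, dim: int, num_heads: int, window: tuple[int, int, int],
                 shifted: bool, rng: np.random.Generator):
        super().__init__()
        self.shifted = shifted
        self.window = tuple(window)
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, num_heads, window, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * 4.0), rng)

    def forward(self, x: Tensor) -> Tensor:
        n, d, h, w, c = x.shape
        ws, ss = _effective_window((d, h, w), self.window, self.shifted)
        x = x + self._windowed_attention(self.norm1(x), ws, ss)
        x = x + self.mlp(self.norm2(x))
        return x

    def _windowed_attention(self, x: Tensor, ws, ss) -> Tensor:
        n, d, h, w, c = x.shape
        pd, ph, pw = [-(-g // s) * s for g, s in zip((d, h, w), ws)]
        if (pd, ph, pw) != (d, h, w):
            x = x.pad(((0, 0), (0, pd - d), (0, ph - h), (0, pw - w), (0, 0)))
        if any(ss):
            x = x.roll(tuple(-s for s in ss), (1, 2, 3))
        mask = _attention_mask((d, h, w), ws, ss)
        t = ws[0] * ws[1] * ws[2]
        x = x.reshape(n, pd // ws[0], ws[0], ph // ws[1], ws[1],
                      pw // ws[2], ws[2], c)
        x = x.transpose(0, 1, 3, 5, 2, 4, 6, 7).reshape(-1, t, c)
        x = self.attn(x, ws, mask)
        x = x.reshape(n, pd // ws[0], ph // ws[1], pw // ws[2],
                      ws[0], ws[1], ws[2], c)
        x = x.transpose(0, 1, 4, 2, 5, 3, 6, 7).reshape(n, pd, ph, pw, c)
        if any(ss):
            x = x.roll(ss, (1, 2, 3))
        if (pd, ph, pw) != (d, h, w):
            x = x[:, :d, :h, :w, :]
        return x


class PatchEmbed(Module):
    """Patch partition + linear embedding (a pure linear map, so the token
    grid is linear in the input)."""

    def __init__(self, in_channels: int, embed_dim: int, patch_size: int,
                 rng: np.random.Generator):
        super().__init__()
        self.patch_size = int(patch_size)
        self.proj = Linear(in_channels * self.patch_size ** 3, embed_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        """(N, C, D, H, W) -> tokens (N, D/p, H/p, W/p, embed_dim)."""
        p = self.patch_size
        n, c, d, h, w = x.shape
        pads = [(-g) % p for g in (d, h, w)]
        if any(pads):
            x = x.pad(((0, 0), (0, 0), (0, pads[0]), (0, pads[1]), (0, pads[2])))
            d, h, w = d + pads[0], h + pads[1], w + pads[2]
        x = x.reshape(n, c, d // p, p, h // p, p, w // p, p)
        x = x.transpose(0, 2, 4, 6, 3, 5, 7, 1)  # (N, d', h', w', p, p, p, C)
        x = x.reshape(n, d // p, h // p, w // p, p ** 3 * c)
        return self.proj(x)


class PatchMerging(Module):
    """Concatenate 2x2x2 neighbouring tokens and reduce 8C -> 2C linearly;
    halves every spatial extent (odd extents are zero-padded first)."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.norm = LayerNorm(8 * dim)
        self.reduction = Linear(8 * dim, 2 * dim, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        n, d, h, w, c = x.shape
        pads = [g % 2 for g in (d, h, w)]
        if any(pads):
            x = x.pad(((0, 0), (0, pads[0]), (0, pads[1]), (0, pads[2]), (0, 0)))
            d, h, w = d + pads[0], h + pads[1], w + pads[2]
        x = x.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c)
        x = x.transpose(0, 1, 3, 5, 2, 4, 6, 7)
        x = x.reshape(n, d // 2, h // 2, w // 2, 8 * c)
        return self.reduction(self.norm(x))


class SwinStage(Module):
    """One encoder stage: optional patch merging, then an even number of
    transformer blocks alternating regular and shifted windows."""

    def __init__(self, dim: int, depth: int, num_heads: int,
                 window: tuple[int, int, int], merge: bool,
                 rng: np.random.Generator):
        super().__init__()
        self.merge = PatchMerging(dim // 2, rng) if merge else None
        self.blocks = ModuleList([
            SwinBlock(dim, num_heads, window, shifted=bool(i % 2), rng=rng)
            for i in range(depth)
        ])

    def forward(self, x: Tensor) -> Tensor:
        if self.merge is not None:
            x = self.merge(x)
        for block in self.blocks:
            x = block(x)
        return x


def tokens_to_map(x: Tensor) -> Tensor:
    """(N, D, H, W, C) tokens -> (N, C, D, H, W) feature map."""
    return x.transpose(0, 4, 1, 2, 3)


class SwinEncoder(Module):
    """Full encoder ladder: levels 0..5 with channels
    (E, E, 2E, 4E, 8E, 16E) at resolutions 1, 1/2, ..., 1/32."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        e = cfg.embed_dim
        # level-0 path: per-voxel projection of the raw modalities to E
        # channels at full resolution
        self.input_proj = Conv3d(cfg.in_channels, e, 1, rng)
        self.patch_embed = PatchEmbed(cfg.in_channels, e, cfg.patch_size, rng)
        dims = [e, 2 * e, 4 * e, 8 * e]
        self.stages = ModuleList([
            SwinStage(dims[i], cfg.depths[i], cfg.num_heads[i],
                      cfg.window_size, merge=(i > 0), rng=rng)
            for i in range(4)
        ])
        self.final_merge = PatchMerging(8 * e, rng)

    def forward(self, x: Tensor) -> list[Tensor]:
        """Volume (N, 4, D, H, W) -> six feature maps, levels 0..5."""
        d, h, w = x.shape[2:]
        if any(g % 32 for g in (d, h, w)) and not getattr(self, "_warned", False):
            self._warned = True
            logger.warning(
                "input extents %s not divisible by 32; merges pad internally "
                "and the decoder crops back", (d, h, w))
        features = [self.input_proj(x)]
        tokens = self.patch_embed(x)
        for stage in self.stages:
            tokens = stage(tokens)
            features.append(tokens_to_map(tokens))
        features.append(tokens_to_map(self.final_merge(tokens)))
        return features
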