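"""Swin encoder: shapes, linearity, window attention and merge semantics."""

import numpy as np
import pytest

from ecatbrats.encoder import (EncoderConfig, PatchEmbed, PatchMerging,
                               SwinBlock, SwinEncoder, SwinStage)
from ecatbrats.nn import Tensor, no_grad


@pytest.fixture
def rng():
    return np.random.default_rng(7)


class TestPatchEmbed:
    def test_print_size_token_grid(self, rng):
        """A (4, 96, 128, 128) volume embeds to a 48-channel half-resolution
        token grid: feature map (48, 48, 64, 64)."""
        embed = PatchEmbed(4, 48, 2, rng)
        x = Tensor(rng.normal(size=(1, 4, 96, 128, 128)).astype(np.float32))
        with no_grad():
            tokens = embed(x)
        assert tokens.shape == (1, 48, 64, 64, 48)  # (N, D', H', W', C)

    def test_zero_input_gives_pure_bias_pattern(self, rng):
        embed = PatchEmbed(4, 8, 2, rng)
        tokens = embed(Tensor(np.zeros((1, 4, 8, 8, 8), dtype=np.float32)))
        np.testing.assert_allclose(tokens.data,
                                   np.broadcast_to(embed.proj.bias.data,
                                                   tokens.shape), atol=1e-7)

    def test_linearity_after_bias_removal(self, rng):
        embed = PatchEmbed(4, 8, 2, rng)
        x = rng.normal(size=(1, 4, 8, 8, 8)).astype(np.float32)
        bias = embed(Tensor(np.zeros_like(x))).data
        y1 = embed(Tensor(x)).data - bias
        y2 = embed(Tensor(2 * x)).data - bias
        np.testing.assert_allclose(y2, 2 * y1, atol=1e-4)


class TestSwinStage:
    def test_channel_sequence_through_merging_stages(self, rng):
        """Stages 2..4 plus the final merge double channels along
        96, 192, 384, 768 while halving each spatial extent."""
        cfg = EncoderConfig()
        tokens = Tensor(rng.normal(size=(1, 8, 8, 8, 48)).astype(np.float32))
        widths = []
        x = tokens
        with no_grad():
            for i in (1, 2, 3):
                stage = SwinStage(cfg.channels(i + 1), cfg.depths[i],
                                  cfg.num_heads[i], (2, 2, 2), merge=True, rng=rng)
                x = stage(x)
                widths.append(x.shape[-1])
            final = PatchMerging(384, rng)
            widths.append(final(x).shape[-1])
        assert widths == [96, 192, 384, 768]

    def test_merge_shrinks_tokens_eightfold(self, rng):
        merge = PatchMerging(8, rng)
        x = Tensor(rng.normal(size=(2, 6, 4, 8, 8)).astype(np.float32))
        y = merge(x)
        assert y.shape == (2, 3, 2, 4, 16)
        n_in = 6 * 4 * 8
        n_out = 3 * 2 * 4
        assert n_in == 8 * n_out

    def test_merge_pads_odd_extents(self, rng):
        merge = PatchMerging(8, rng)
        y = merge(Tensor(rng.normal(size=(1, 5, 4, 3, 8)).astype(np.float32)))
        assert y.shape == (1, 3, 2, 2, 16)

    def test_identity_initialised_blocks_reduce_to_patch_merging(self, rng):
        """Zeroing both residual branches (attention projection, MLP output)
        makes the stage equal its merge layer alone."""
        stage = SwinStage(16, depth=2, num_heads=2, window=(2, 2, 2),
                          merge=True, rng=rng)
        for block in stage.blocks:
            block.attn.proj.weight.data[:] = 0
            block.attn.proj.bias.data[:] = 0
            block.mlp.fc2.weight.data[:] = 0
            block.mlp.fc2.bias.data[:] = 0
        x = Tensor(rng.normal(size=(1, 4, 4, 4, 8)).astype(np.float32))
        with no_grad():
            full = stage(x)
            merged = stage.merge(x)
        np.testing.assert_allclose(full.data, merged.data, atol=1e-6)


class TestWindowAttention:
    def test_attention_weights_sum_to_one(self, rng):
        block = SwinBlock(8, 2, (3, 3, 3), shifted=True, rng=rng)
        block.attn.store_attn = True
        x = Tensor(rng.normal(size=(1, 5, 6, 7, 8)).astype(np.float32))
        with no_grad():
            block(x)
        sums = block.attn.last_attn.sum(axis=-1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-5)

    def test_full_window_translation_equivariance(self, rng):
        """In non-shifted blocks, translating the token grid by one whole
        window translates the output identically (cyclic roll)."""
        block = SwinBlock(8, 2, (2, 2, 2), shifted=False, rng=rng)
        x = rng.normal(size=(1, 4, 4, 4, 8)).astype(np.float32)
        with no_grad():
            y = block(Tensor(x)).data
            y_rolled = block(Tensor(np.roll(x, (2, 2, 2), axis=(1, 2, 3)))).data
        np.testing.assert_allclose(y_rolled, np.roll(y, (2, 2, 2), axis=(1, 2, 3)),
                                   atol=1e-5)

    def test_shifted_block_differs_from_regular(self, rng):
        xr = rng.normal(size=(1, 4, 4, 4, 8)).astype(np.float32)
        regular = SwinBlock(8, 2, (2, 2, 2), shifted=False, rng=np.random.default_rng(0))
        shifted = SwinBlock(8, 2, (2, 2, 2), shifted=True, rng=np.random.default_rng(0))
        # force distinct attention content so the partition matters
        regular.attn.qkv.weight.data[:] = shifted.attn.qkv.weight.data
        with no_grad():
            assert not np.allclose(regular(Tensor(xr)).data,
                                   shifted(Tensor(xr)).data)


class TestEncode:
    def test_halving_ladder_shapes(self, rng):
        cfg = EncoderConfig(embed_dim=8, num_heads=(2, 2, 2, 2),
                            window_size=(4, 4, 4))
        enc = SwinEncoder(cfg, rng)
        x = Tensor(rng.normal(size=(1, 4, 32, 32, 32)).astype(np.float32))
        with no_grad():
            feats = enc(x)
        shapes = [f.shape for f in feats]
        assert shapes == [(1, 8, 32, 32, 32), (1, 8, 16, 16, 16),
                          (1, 16, 8, 8, 8), (1, 32, 4, 4, 4),
                          (1, 64, 2, 2, 2), (1, 128, 1, 1, 1)]

    def test_encode_is_deterministic(self, rng):
        cfg = EncoderConfig(embed_dim=8, num_heads=(2, 2, 2, 2),
                            window_size=(2, 2, 2))
        enc = SwinEncoder(cfg, np.random.default_rng(3))
        x = Tensor(rng.normal(size=(1, 4, 16, 16, 16)).astype(np.float32))
        with no_grad():
            a = enc(x)
            b = enc(x)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.data, fb.data)

    def test_channel_ladder_matches_config(self):
        cfg = EncoderConfig(embed_dim=48)
        assert [cfg.channels(level) for level in range(6)] == \
            [48, 48, 96, 192, 384, 768]

    def test_all_encoder_parameters_receive_gradient(self, rng):
        """No dead branches: with a non-degenerate window geometry (windows
        holding more than one token at every level), every parameter gets a
        nonzero gradient."""
        cfg = EncoderConfig(embed_dim=8, num_heads=(2, 2, 2, 2),
                            window_size=(4, 4, 4))
        enc = SwinEncoder(cfg, np.random.default_rng(5))
        x = Tensor(rng.normal(size=(1, 4, 32, 32, 32)).astype(np.float32))
        feats = enc(x)
        loss = feats[0].sum()
        for f in feats[1:]:
            loss = loss + (f * f).sum()
        loss.backward()
        missing = [n for n, p in enc.named_parameters()
                   if p.grad is None or not np.any(p.grad)]
        assert not missing, f"dead parameters: {missing}"
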