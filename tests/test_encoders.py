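"""CNN-branch pyramid encoder and transformer encoder."""

import numpy as np
import pytest

from psnet.config import PSNetConfig, ViTConfig
from psnet.nn import Tensor, no_grad
from psnet.ps_encoder import PSEncoder
from psnet.vit import (ViTEncoder, inverse_patchify, load_pretrained, patchify,
                       CheckpointError)


class TestPSEncoder:
    def test_four_scale_pyramid_with_channel_schedule(self, rng):
        enc = PSEncoder(PSNetConfig.tiny()).eval()
        x = Tensor(rng.standard_normal((1, 3, 64, 64)).astype(np.float32))
        with no_grad():
            feats = enc(x)
        shapes = [f.shape for f in feats]
        assert shapes == [(1, 64, 32, 32), (1, 128, 16, 16),
                          (1, 256, 8, 8), (1, 512, 4, 4)]

    def test_indivisible_input_rejected_before_compute(self):
        enc = PSEncoder(PSNetConfig.tiny())
        with pytest.raises(ValueError, match="divisible by 16"):
            enc(Tensor(np.zeros((1, 3, 50, 50), dtype=np.float32)))

    def test_wrong_channel_count_rejected(self):
        enc = PSEncoder(PSNetConfig.tiny())
        with pytest.raises(ValueError, match="3-channel"):
            enc(Tensor(np.zeros((1, 4, 64, 64), dtype=np.float32)))

    def test_parameter_count_grows_with_channel_schedule(self):
        small = PSEncoder(PSNetConfig.tiny(encoder_channels=(16, 32, 64, 128),
                                           decoder_channels=(64, 32, 16, 8)))
        large = PSEncoder(PSNetConfig.tiny())
        assert small.num_parameters() < large.num_parameters()


class TestPatchify:
    @pytest.mark.parametrize("size,patch,n", [(512, 16, 1024), (64, 16, 16)])
    def test_token_count(self, rng, size, patch, n):
        x = Tensor(rng.standard_normal((1, 3, size, size)).astype(np.float32))
        assert patchify(x, patch).shape == (1, n, 3 * patch * patch)

    def test_round_trip_is_exact(self, rng):
        x = rng.standard_normal((2, 3, 32, 32)).astype(np.float32)
        tokens = patchify(Tensor(x), 16)
        back = inverse_patchify(tokens, 16, 32, 32)
        assert np.array_equal(back.data, x)

    def test_indivisible_dims_rejected(self):
        with pytest.raises(ValueError, match="patch"):
            patchify(Tensor(np.zeros((1, 3, 30, 30), dtype=np.float32)), 16)


class TestAttention:
    def test_rows_sum_to_one(self, rng):
        enc = ViTEncoder(ViTConfig.tiny(), image_size=64)
        for block in enc.blocks:
            block.attn.store_attn = True
        x = Tensor(rng.standard_normal((1, 3, 64, 64)).astype(np.float32))
        with no_grad():
            enc(x)
        for block in enc.blocks:
            assert np.allclose(block.attn.attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_single_token_attention_is_exactly_one(self, rng):
        from psnet.vit import Attention
        attn = Attention(8, 2)
        attn.store_attn = True
        with no_grad():
            attn(Tensor(rng.standard_normal((1, 1, 8)).astype(np.float32)))
        assert np.array_equal(attn.attn, np.ones((1, 2, 1, 1), dtype=np.float32))

    def test_permutation_equivariance_without_positions(self, rng):
        """With positional embeddings zeroed, token order commutes with blocks."""
        enc = ViTEncoder(ViTConfig.tiny(), image_size=64).eval()
        enc.pos_embed.data[:] = 0.0
        x = Tensor(rng.standard_normal((1, 3, 64, 64)).astype(np.float32))
        perm = rng.permutation(16)
        with no_grad():
            tokens = enc.patchify_embed(x)
            out = tokens
            for b in enc.blocks:
                out = b(out)
            permuted = Tensor(tokens.data[:, perm])
            out_p = permuted
            for b in enc.blocks:
                out_p = b(out_p)
        assert np.allclose(out.data[:, perm], out_p.data, atol=1e-5)

    def test_two_token_hand_oracle(self, rng):
        """Single-head attention against a hand-rolled softmax(QK^T/sqrt d)V."""
        from psnet.vit import Attention
        attn = Attention(4, 1).eval()
        x = rng.standard_normal((1, 2, 4)).astype(np.float32)
        with no_grad():
            out = attn(Tensor(x)).data
        W = {n: p.data for n, p in attn.named_parameters()}
        q = x[0] @ W["q.weight"].T + W["q.bias"]
        k = x[0] @ W["k.weight"].T + W["k.bias"]
        v = x[0] @ W["v.weight"].T + W["v.bias"]
        scores = q @ k.T / 2.0
        e = np.exp(scores - scores.max(axis=-1, keepdims=True))
        ref = (e / e.sum(axis=-1, keepdims=True)) @ v
        ref = ref @ W["proj.weight"].T + W["proj.bias"]
        assert np.abs(out[0] - ref).max() < 1e-5


class TestViTEncoder:
    def test_tiny_shape_and_determinism(self, rng):
        enc = ViTEncoder(ViTConfig.tiny(), image_size=64).eval()
        x = Tensor(rng.standard_normal((1, 3, 64, 64)).astype(np.float32))
        with no_grad():
            a = enc(x).data
            b = enc(x).data
        assert a.shape == (1, 16, 64)
        assert np.array_equal(a, b)

    def test_token_count_conserved_through_blocks(self, rng):
        enc = ViTEncoder(ViTConfig.tiny(), image_size=64)
        x = Tensor(rng.standard_normal((1, 3, 64, 64)).astype(np.float32))
        with no_grad():
            tokens = enc.patchify_embed(x)
            for block in enc.blocks:
                tokens = block(tokens)
                assert tokens.shape == (1, 16, 64)


class TestPretrainedLoading:
    def test_round_trip_loads_everything(self, tmp_path):
        enc = ViTEncoder(ViTConfig.tiny(), image_size=64)
        path = tmp_path / "ckpt.npz"
        np.savez(path, **enc.state_dict())
        report = load_pretrained(enc, path)
        assert report.missing == [] and report.resized == []
        assert len(report.loaded) == len(enc.state_dict())

    def test_pos_embed_interpolated_across_grids(self):
        cfg = ViTConfig.tiny()
        src = ViTEncoder(cfg, image_size=64)    # 4x4 grid
        dst = ViTEncoder(cfg, image_size=128)   # 8x8 grid
        report = load_pretrained(dst, src.state_dict())
        assert "pos_embed" in report.resized
        assert dst.pos_embed.data.shape == (1, 64, cfg.embed_dim)

    def test_corrupt_checkpoint_raises_with_context(self, tmp_path):
        bad = tmp_path / "bad.npz"
        bad.write_bytes(b"not a checkpoint")
        enc = ViTEncoder(ViTConfig.tiny(), image_size=64)
        with pytest.raises(CheckpointError, match="bad.npz"):
            load_pretrained(enc, bad)

    def test_extra_and_missing_tensors_reported_not_fatal(self):
        enc = ViTEncoder(ViTConfig.tiny(), image_size=64)
        state = enc.state_dict()
        state.pop("norm.weight")
        state["stray"] = np.zeros(3)
        report = load_pretrained(enc, state)
        assert report.missing == ["norm.weight"]
        assert report.unused == ["stray"]
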