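"""Transformer-branch decoders, CNN decoder, attention gates, merge modules."""

import numpy as np
import pytest

from psnet.config import PSNetConfig, ViTConfig, WSqConfig
from psnet.merge import MergeModule
from psnet.nn import Tensor, no_grad, sigmoid
from psnet.nn.functional import avg_pool2d
from psnet.ps_decoder import SCSE, PSDecoder, WSq
from psnet.ps_encoder import PSEncoder
from psnet.transformer_decoder import EnhancedDecoder, PartialDecoder


class TestPartialDecoder:
    def test_projects_tokens_to_logit_grid(self, rng):
        pd = PartialDecoder(embed_dim=768, mu=64)
        tokens = Tensor(rng.standard_normal((1, 1024, 768)).astype(np.float32))
        assert pd(tokens).shape == (1, 64, 32, 32)

    def test_single_tissue_logit(self, rng):
        pd = PartialDecoder(embed_dim=64, mu=1)
        tokens = Tensor(rng.standard_normal((1, 1024, 64)).astype(np.float32))
        assert pd(tokens).shape == (1, 1, 32, 32)

    def test_rearrangement_round_trips(self, rng):
        pd = PartialDecoder(embed_dim=8, mu=5)
        tokens = Tensor(rng.standard_normal((2, 16, 8)).astype(np.float32))
        with no_grad():
            grid = pd(tokens).data
            flat = pd.proj(tokens).data
        # (b, mu, s, s) back to (b, N, mu), row-major
        recovered = grid.transpose(0, 2, 3, 1).reshape(2, 16, 5)
        assert np.array_equal(recovered, flat)

    def test_non_square_token_count_rejected(self, rng):
        pd = PartialDecoder(embed_dim=8, mu=4)
        with pytest.raises(ValueError, match="perfect square"):
            pd(Tensor(np.zeros((1, 15, 8), dtype=np.float32)))

    def test_linearity_with_zero_bias(self, rng):
        pd = PartialDecoder(embed_dim=8, mu=4)
        pd.proj.bias.data[:] = 0
        t = rng.standard_normal((1, 16, 8)).astype(np.float32)
        with no_grad():
            assert np.allclose(pd(Tensor(3.0 * t)).data, 3.0 * pd(Tensor(t)).data,
                               atol=1e-5)


class TestEnhancedDecoder:
    def test_full_and_tiny_scales(self, rng):
        dec = EnhancedDecoder(PSNetConfig.tiny()).eval()
        grid = Tensor(rng.standard_normal((1, 64, 4, 4)).astype(np.float32))
        with no_grad():
            assert dec(grid).shape == (1, 1, 64, 64)

    def test_wrong_scale_rejected(self, rng):
        dec = EnhancedDecoder(PSNetConfig.tiny())
        with pytest.raises(ValueError, match="1/16 scale"):
            dec(Tensor(np.zeros((1, 64, 8, 8), dtype=np.float32)))

    def test_zero_parameters_give_zero_map(self):
        dec = EnhancedDecoder(PSNetConfig.tiny()).eval()
        for _, p in dec.named_parameters():
            p.data[:] = 0
        with no_grad():
            out = dec(Tensor(np.random.default_rng(0).standard_normal(
                (1, 64, 4, 4)).astype(np.float32)))
        assert np.abs(out.data).max() == 0.0


class TestWSq:
    def _stepwise_oracle(self, mod, x):
        """Compose WAP -> PW -> PW -> sigmoid and PW -> sigmoid by hand."""
        c = mod.cfg
        with no_grad():
            pooled = avg_pool2d(Tensor(x), c.kernel, stride=c.stride,
                                padding=c.padding)
            gate_a = sigmoid(mod.pw_a2(mod.pw_a1(pooled))).data
            gate_b = sigmoid(mod.pw_b(Tensor(x))).data
        return x * gate_a + x * gate_b

    def test_matches_composition_oracle(self, rng):
        mod = WSq(8).eval()
        for _, p in mod.named_parameters():
            p.data = rng.standard_normal(p.data.shape).astype(np.float32) * 0.5
        x = rng.standard_normal((1, 8, 16, 16)).astype(np.float32)
        with no_grad():
            out = mod(Tensor(x)).data
        assert np.abs(out - self._stepwise_oracle(mod, x)).max() < 1e-6

    def test_saturated_gates_double_or_zero_input(self, rng):
        mod = WSq(4).eval()
        x = rng.standard_normal((1, 4, 8, 8)).astype(np.float32)
        for bias, factor in ((40.0, 2.0), (-40.0, 0.0)):
            mod.pw_a2.bias.data[:] = bias
            mod.pw_a2.weight.data[:] = 0
            mod.pw_b.bias.data[:] = bias
            mod.pw_b.weight.data[:] = 0
            with no_grad():
                out = mod(Tensor(x)).data
            assert np.allclose(out, factor * x, atol=1e-6)

    def test_preserves_shape(self, rng):
        mod = WSq(8, WSqConfig(kernel=5, padding=2))
        x = Tensor(rng.standard_normal((2, 8, 12, 12)).astype(np.float32))
        assert mod(x).shape == (2, 8, 12, 12)

    def test_reduction_collapse_rejected(self):
        with pytest.raises(ValueError):
            WSq(1)


class TestSCSE:
    def test_matches_composition_oracle(self, rng):
        from psnet.nn import relu
        mod = SCSE(8).eval()
        for _, p in mod.named_parameters():
            p.data = rng.standard_normal(p.data.shape).astype(np.float32) * 0.5
        x = rng.standard_normal((1, 8, 6, 6)).astype(np.float32)
        with no_grad():
            pooled = Tensor(x.mean(axis=(2, 3), keepdims=True))
            cgate = sigmoid(mod.fc2(relu(mod.fc1(pooled)))).data
            sgate = sigmoid(mod.spatial(Tensor(x))).data
            out = mod(Tensor(x)).data
        assert np.abs(out - (x * cgate + x * sgate)).max() < 1e-6

    def test_constant_channels_give_spatially_constant_output(self):
        mod = SCSE(4).eval()
        x = np.ones((1, 4, 6, 6), dtype=np.float32) * \
            np.arange(1, 5, dtype=np.float32)[None, :, None, None]
        with no_grad():
            out = mod(Tensor(x)).data
        assert np.allclose(out, out[:, :, :1, :1], atol=1e-6)


class TestPSDecoder:
    def test_tiny_pyramid_to_full_resolution_map(self, rng, tiny_cfg):
        enc = PSEncoder(tiny_cfg).eval()
        dec = PSDecoder(tiny_cfg).eval()
        x = Tensor(rng.standard_normal((1, 3, 64, 64)).astype(np.float32))
        with no_grad():
            out = dec(enc(x))
        assert out.shape == (1, 1, 64, 64)

    def test_wrong_deep_channels_rejected(self, tiny_cfg):
        dec = PSDecoder(tiny_cfg)
        bad = [Tensor(np.zeros((1, c, s, s), dtype=np.float32))
               for c, s in ((64, 32), (128, 16), (256, 8), (100, 4))]
        with pytest.raises(ValueError, match="channels"):
            dec(bad)

    def test_skip_connections_are_live(self, rng, tiny_cfg):
        # train-mode batch norm keeps activation scale healthy in an
        # untrained network, so a perturbed skip must move the output
        enc = PSEncoder(tiny_cfg).train()
        dec = PSDecoder(tiny_cfg).train()
        x = Tensor(rng.standard_normal((2, 3, 64, 64)).astype(np.float32))
        with no_grad():
            pyramid = enc(x)
            ref = dec(pyramid).data
            zeroed = list(pyramid)
            zeroed[0] = Tensor(np.zeros_like(pyramid[0].data))
            out = dec(zeroed).data
        assert np.abs(out - ref).max() > 1e-6


class TestMerge:
    @pytest.mark.parametrize("scale,channels,size", [(16, 512, 4), (8, 256, 8),
                                                     (4, 128, 16), (2, 64, 32)])
    def test_each_scale_reaches_full_resolution(self, rng, tiny_cfg,
                                                scale, channels, size):
        mod = MergeModule(tiny_cfg, scale, ps_channels=channels).eval()
        ps = Tensor(rng.standard_normal((1, channels, size, size)).astype(np.float32))
        grid = Tensor(rng.standard_normal((1, 64, 4, 4)).astype(np.float32))
        with no_grad():
            out = mod(ps, grid)
        assert out.shape == (1, 1, 64, 64)

    def test_internal_width_constant_at_64(self, rng, tiny_cfg):
        mod = MergeModule(tiny_cfg, 2, ps_channels=64).eval()
        ps = Tensor(rng.standard_normal((1, 64, 32, 32)).astype(np.float32))
        grid = Tensor(rng.standard_normal((1, 64, 4, 4)).astype(np.float32))
        with no_grad():
            mod(ps, grid)
        assert mod.internal_channels == [64] * 5

    def test_scale_mismatch_rejected(self, rng, tiny_cfg):
        mod = MergeModule(tiny_cfg, 4, ps_channels=128)
        ps = Tensor(np.zeros((1, 128, 8, 8), dtype=np.float32))  # 1/8, not 1/4
        grid = Tensor(np.zeros((1, 64, 4, 4), dtype=np.float32))
        with pytest.raises(ValueError, match="scale"):
            mod(ps, grid)

    def test_parameter_counts_equal_except_entry_projection(self, tiny_cfg):
        mods = [MergeModule(tiny_cfg, s, ps_channels=c)
                for s, c in ((16, 512), (8, 256), (4, 128), (2, 64))]
        body = [m.num_parameters() - m.proj.num_parameters() for m in mods]
        assert len(set(body)) == 1
        assert len({m.proj.num_parameters() for m in mods}) == 4
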