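"""Full assembly: candidate streams, averaging, loss, metrics, variants."""

import numpy as np
import pytest

from psnet.config import PSNetConfig
from psnet.model import (PSNet, average_streams, build_variant, dice_iou,
                         iou_loss, load_checkpoint, save_checkpoint)
from psnet.nn import Tensor, no_grad


STREAM_NAMES = {"transformer", "cnn", "merge_1/16", "merge_1/8",
                "merge_1/4", "merge_1/2"}


def _loop_iou_loss(logits, y, eps=1e-6):
    """Per-pixel loop oracle for 1 − softIoU."""
    p = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
    inter = union = 0.0
    for pi, yi in zip(p.ravel(), y.ravel()):
        inter += pi * yi
        union += pi + yi - pi * yi
    return 1.0 - (inter + eps) / (union + eps)


class TestForward:
    def test_six_streams_at_tiny_scale(self, rng, tiny_model):
        x = Tensor(rng.standard_normal((1, 3, 64, 64)).astype(np.float32))
        tiny_model.eval()
        with no_grad():
            out = tiny_model(x)
        assert set(out.streams) == STREAM_NAMES
        assert all(s.shape == (1, 1, 64, 64) for s in out.streams.values())
        assert out.mean.shape == (1, 1, 64, 64)

    def test_mean_of_constant_streams(self):
        streams = [Tensor(np.full((1, 1, 4, 4), float(v))) for v in range(6)]
        mean = average_streams(streams)
        assert np.allclose(mean.data, 2.5)

    def test_forward_is_deterministic_in_inference(self, rng, tiny_model):
        x = Tensor(rng.standard_normal((1, 3, 64, 64)).astype(np.float32))
        tiny_model.eval()
        with no_grad():
            a = tiny_model(x).mean.data
            b = tiny_model(x).mean.data
        assert np.array_equal(a, b)

    def test_wrong_image_size_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="configured for 64x64"):
            tiny_model(Tensor(np.zeros((1, 3, 32, 32), dtype=np.float32)))


class TestIoULoss:
    def test_perfect_prediction_limit(self):
        y = (np.random.default_rng(0).random((1, 1, 8, 8)) > 0.5).astype(np.float32)
        logits = np.where(y > 0, 20.0, -20.0).astype(np.float32)
        assert iou_loss(Tensor(logits), y).item() < 1e-6

    def test_empty_mask_convention(self):
        # with an all-zero mask, loss = 1 − ε/(Σσ + ε) → 0 as Σσ → 0
        y = np.zeros((1, 1, 8, 8), dtype=np.float32)
        strong = np.full((1, 1, 8, 8), -40.0, dtype=np.float32)
        assert iou_loss(Tensor(strong), y).item() < 1e-6
        mild = np.full((1, 1, 8, 8), -20.0, dtype=np.float32)
        sigma_sum = 64 * 1.0 / (1.0 + np.exp(20.0))
        expected = 1.0 - 1e-6 / (sigma_sum + 1e-6)
        assert iou_loss(Tensor(mild), y).item() == pytest.approx(expected, rel=1e-3)

    def test_hand_case_2x2(self):
        # sigma(0) = 0.5 everywhere; y has one positive pixel:
        # soft-I = 0.5, soft-U = 2.5, loss = 1 - 0.2 = 0.8
        logits = np.zeros((1, 1, 2, 2), dtype=np.float32)
        y = np.array([[[[1, 0], [0, 0]]]], dtype=np.float32)
        assert iou_loss(Tensor(logits), y).item() == pytest.approx(0.8, abs=1e-6)

    @pytest.mark.parametrize("case", range(10))
    def test_matches_per_pixel_loop_oracle(self, case):
        rng = np.random.default_rng(100 + case)
        logits = rng.standard_normal((1, 1, 8, 8)).astype(np.float32) * 3
        y = (rng.random((1, 1, 8, 8)) > 0.5).astype(np.float32)
        got = iou_loss(Tensor(logits), y).item()
        assert got == pytest.approx(_loop_iou_loss(logits, y), abs=1e-6)

    def test_monotone_towards_zero_with_logit_magnitude(self):
        y = (np.random.default_rng(1).random((1, 1, 8, 8)) > 0.5).astype(np.float32)
        losses = [iou_loss(Tensor(np.where(y > 0, m, -m).astype(np.float32)), y).item()
                  for m in (1.0, 2.0, 4.0, 8.0, 16.0)]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_non_binary_mask_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            iou_loss(Tensor(np.zeros((1, 1, 2, 2))),
                     np.full((1, 1, 2, 2), 0.5, dtype=np.float32))

    def test_differentiable_in_logits(self):
        logits = Tensor(np.zeros((1, 1, 4, 4), dtype=np.float32))
        logits.requires_grad = True
        y = np.ones((1, 1, 4, 4), dtype=np.float32)
        iou_loss(logits, y).backward()
        assert np.all(logits.grad != 0)


class TestDiceIoU:
    def test_identical_and_disjoint(self):
        a = np.zeros((8, 8), dtype=np.uint8)
        a[:2] = 1
        b = np.zeros((8, 8), dtype=np.uint8)
        b[4:] = 1
        assert dice_iou(a, a) == (1.0, 1.0)
        assert dice_iou(a, b) == (0.0, 0.0)

    def test_counting_case(self):
        p = np.zeros(10, dtype=np.uint8)
        g = np.zeros(10, dtype=np.uint8)
        p[:4] = 1
        g[2:6] = 1  # |P|=4, |G|=4, |P∩G|=2
        d, i = dice_iou(p, g)
        assert d == pytest.approx(0.5)
        assert i == pytest.approx(1 / 3)

    def test_empty_vs_empty_scores_one(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        assert dice_iou(z, z) == (1.0, 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_dice_iou_identity_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            p = (rng.random((6, 6)) > rng.random()).astype(np.uint8)
            g = (rng.random((6, 6)) > rng.random()).astype(np.uint8)
            d, i = dice_iou(p, g)
            assert d >= i
            assert d == pytest.approx(2 * i / (1 + i), abs=1e-12)


class TestVariants:
    @pytest.mark.parametrize("variant,expected_streams", [
        ("no_transformer", 5),   # cnn + 4 merges
        ("no_dual_decoder", 1),  # single fused stream
        ("no_merge", 2),         # transformer + cnn
        ("no_ps_encoder", 5),    # transformer + 4 merges
        ("no_ccm", 6),
        ("full", 6),
    ])
    def test_stream_counts_and_parameter_ordering(self, rng, tiny_cfg, variant,
                                                  expected_streams):
        full = build_variant(tiny_cfg, "full")
        model = build_variant(tiny_cfg, variant).eval()
        x = Tensor(rng.standard_normal((1, 3, 64, 64)).astype(np.float32))
        with no_grad():
            out = model(x)
        assert len(out.streams) == expected_streams
        if variant != "full":
            assert model.num_parameters() < full.num_parameters()

    def test_no_transformer_has_no_vit_tensors(self, tiny_cfg):
        model = build_variant(tiny_cfg, "no_transformer")
        assert not [n for n, _ in model.named_parameters() if n.startswith("vit.")]

    def test_unknown_variant_rejected(self, tiny_cfg):
        with pytest.raises(ValueError, match="unknown variant"):
            build_variant(tiny_cfg, "no_everything")

    def test_ablation_mean_renormalizes(self, rng, tiny_cfg):
        model = build_variant(tiny_cfg, "no_merge").eval()
        x = Tensor(rng.standard_normal((1, 3, 64, 64)).astype(np.float32))
        with no_grad():
            out = model(x)
        manual = (out.streams["transformer"].data + out.streams["cnn"].data) / 2
        assert np.allclose(out.mean.data, manual, atol=1e-6)


class TestDeepSupervisionGradients:
    def test_every_parameter_of_every_branch_gets_gradient(self, rng, tiny_cfg):
        """One backward pass reaches all six streams' parameters.

        Batch 2: per-channel batch statistics need more than one sample at
        the deepest merge scale, where maps collapse to 1x1.
        """
        from psnet.train import init_weights
        model = PSNet(tiny_cfg)
        init_weights(model, seed=3)
        model.train()
        x = Tensor(rng.standard_normal((2, 3, 64, 64)).astype(np.float32))
        y = (rng.random((2, 1, 64, 64)) > 0.7).astype(np.float32)
        model.zero_grad()
        iou_loss(model(x).mean, y).backward()
        dead = [n for n, p in model.named_parameters()
                if p.grad is None or not np.any(p.grad)]
        assert dead == []


class TestCheckpoint:
    def test_round_trip_preserves_outputs(self, rng, tiny_model, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_model, path)
        clone = load_checkpoint(path)
        x = Tensor(rng.standard_normal((1, 3, 64, 64)).astype(np.float32))
        tiny_model.eval()
        clone.eval()
        with no_grad():
            assert np.array_equal(tiny_model(x).mean.data, clone(x).mean.data)
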