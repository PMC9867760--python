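"""Transformer-branch decoding: partial decoder + enhanced dilated decoder.

The partial decoder maps each of the N patch tokens through a pointwise
linear layer to μ tissue logits (μ is a hyperparameter, default 64 — each
logit channel can specialize on a pixel condition such as boundary or
highlight) and rearranges the (N, μ) matrix row-major into a (μ, √N, √N)
grid at 1/16 of the input resolution.

The enhanced dilated transformer decoder then brings that grid to a
full-resolution single-channel candidate map: upsample ×4 → double standard
convolution → upsample ×4 → double dilated convolution (rate 3) → two
pointwise convolutions.
"""

from __future__ import annotations

import math

from .config import PSNetConfig
from .nn import (BatchNorm2d, Conv2d, Linear, Module, Sequential, SiLU,
                 Tensor, Upsample)

__all__ = ["PartialDecoder", "EnhancedDecoder"]


class PartialDecoder(Module):
    """Pointwise token→logit projection + 2-D rearrangement."""

    def __init__(self, embed_dim: int, mu: int):
        super().__init__()
        if mu < 1:
            raise ValueError("mu must be >= 1")
        self.mu = mu
        self.proj = Linear(embed_dim, mu)

    def forward(self, tokens: Tensor) -> Tensor:
        b, n, _ = tokens.shape
        side = int(round(math.sqrt(n)))
        if side * side != n:
            raise ValueError(f"token count {n} is not a perfect square")
        logits = self.proj(tokens)                      # (b, N, mu)
        grid = logits.reshape(b, side, side, self.mu)   # row-major
        return grid.transpose(0, 3, 1, 2)               # (b, mu, side, side)


def _double_conv(in_ch: int, out_ch: int, dilation: int = 1) -> Sequential:
    pad = dilation  # 3x3 kernel: d·(k−1)/2 = d
    return Sequential(
        Conv2d(in_ch, out_ch, 3, padding=pad, dilation=dilation, bias=False),
        BatchNorm2d(out_ch), SiLU(),
        Conv2d(out_ch, out_ch, 3, padding=pad, dilation=dilation, bias=False),
        BatchNorm2d(out_ch), SiLU(),
    )


class EnhancedDecoder(Module):
    """1/16-scale μ-logit grid → full-resolution candidate map (pre-activation)."""

    def __init__(self, cfg: PSNetConfig, width: int = 64, dilation: int = 3):
        super().__init__()
        f1, f2 = cfg.enhanced_up_factors
        self.total_scale = f1 * f2
        if self.total_scale != 16:
            raise ValueError("upsampling factors must compose to x16")
        self.up1 = Upsample(f1)
        self.conv_standard = _double_conv(cfg.mu, width)
        self.up2 = Upsample(f2)
        self.conv_dilated = _double_conv(width, width, dilation=dilation)
        self.pw1 = Conv2d(width, width // 2, 1)
        self.pw_norm = BatchNorm2d(width // 2)
        self.pw_act = SiLU()
        self.pw2 = Conv2d(width // 2, 1, 1)
        self.expected_scale = cfg.image_size // 16

    def forward(self, grid: Tensor) -> Tensor:
        _, _, h, w = grid.shape
        if h != self.expected_scale or w != self.expected_scale:
            raise ValueError(f"grid is {h}x{w} but the configured 1/16 scale is "
                             f"{self.expected_scale}x{self.expected_scale}")
        x = self.conv_standard(self.up1(grid))
        x = self.conv_dilated(self.up2(x))
        x = self.pw_act(self.pw_norm(self.pw1(x)))
        return self.pw2(x)
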