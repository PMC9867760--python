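"""Merge modules: multi-scale fusion of the two encoder branches.

One merge module per pyramid scale s ∈ {1/2, 1/4, 1/8, 1/16}.  The
partial-decoder logit grid (1/16 scale) is bilinearly resized to s,
channel-concatenated with the CNN-branch feature map at s, projected to a
constant internal width of 64 channels, passed through two (maxpool → double
DWSC) steps and two (upsample → double DWSC) steps (returning to scale s),
then upsampled to full resolution and reduced to a single-channel candidate
map.  Each scale owns an independent parameter set.
"""

from __future__ import annotations

from .blocks import DepthwiseSeparableConv
from .config import PSNetConfig
from .nn import (BatchNorm2d, Conv2d, Module, Sequential, SiLU, Tensor,
                 concat, max_pool2d, resize_bilinear)

__all__ = ["MergeModule"]


class MergeModule(Module):
    def __init__(self, cfg: PSNetConfig, scale_denom: int,
                 ps_channels: int | None, use_grid: bool = True):
        """``ps_channels=None`` drops the CNN input; ``use_grid=False`` drops
        the transformer input (ablation re-routings)."""
        super().__init__()
        if scale_denom not in (2, 4, 8, 16):
            raise ValueError(f"unsupported merge scale 1/{scale_denom}")
        if ps_channels is None and not use_grid:
            raise ValueError("merge module needs at least one input branch")
        width = cfg.merge_channels
        in_ch = (ps_channels or 0) + (cfg.mu if use_grid else 0)
        self.scale_denom = scale_denom
        self.use_grid = use_grid
        self.ps_channels = ps_channels
        self.image_size = cfg.image_size
        self.proj = Sequential(Conv2d(in_ch, width, 1, bias=False),
                               BatchNorm2d(width), SiLU())
        self.down_convs = Sequential(
            *[DepthwiseSeparableConv(width, width) for _ in range(2)])
        self.down_convs2 = Sequential(
            *[DepthwiseSeparableConv(width, width) for _ in range(2)])
        self.up_convs = Sequential(
            *[DepthwiseSeparableConv(width, width) for _ in range(2)])
        self.up_convs2 = Sequential(
            *[DepthwiseSeparableConv(width, width) for _ in range(2)])
        self.reduce = Conv2d(width, 1, 1)
        self.internal_channels: list[int] = []  # introspection: widths seen in forward

    def forward(self, ps_feat: Tensor | None, trans_grid: Tensor | None) -> Tensor:
        size = self.image_size // self.scale_denom
        parts = []
        if self.ps_channels is not None:
            if ps_feat is None:
                raise ValueError("merge module configured for a CNN input but got none")
            if ps_feat.shape[2:] != (size, size):
                raise ValueError(
                    f"CNN feature at {ps_feat.shape[2:]} does not match declared "
                    f"scale 1/{self.scale_denom} ({size}x{size})")
            parts.append(ps_feat)
        if self.use_grid:
            if trans_grid is None:
                raise ValueError("merge module configured for a transformer input "
                                 "but got none")
            parts.append(resize_bilinear(trans_grid, (size, size)))
        x = parts[0] if len(parts) == 1 else concat(parts, axis=1)
        x = self.proj(x)
        self.internal_channels = [x.shape[1]]
        x = self.down_convs(max_pool2d(x, 2))
        self.internal_channels.append(x.shape[1])
        x = self.down_convs2(max_pool2d(x, 2))
        self.internal_channels.append(x.shape[1])
        _, _, h, w = x.shape
        x = self.up_convs(resize_bilinear(x, (h * 2, w * 2)))
        self.internal_channels.append(x.shape[1])
        x = self.up_convs2(resize_bilinear(x, (h * 4, w * 4)))
        self.internal_channels.append(x.shape[1])
        x = resize_bilinear(x, (self.image_size, self.image_size))
        return self.reduce(x)
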