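"""CNN branch of the dual encoder.

Four identical (maxpool → LFE) stages turn an RGB frame into a four-scale
feature pyramid at 1/2 … 1/16 resolution with a doubling channel schedule
(default 64, 128, 256, 512).  Every stage output is exposed: the decoder
consumes them as skip connections and the merge modules fuse them with the
transformer branch.
"""

from __future__ import annotations

from .blocks import LFE
from .config import PSNetConfig
from .nn import MaxPool2d, Module, ModuleList, Tensor

__all__ = ["PSEncoder"]


class PSEncoder(Module):
    def __init__(self, cfg: PSNetConfig):
        super().__init__()
        self.in_channels = cfg.in_channels
        channels = (cfg.in_channels,) + cfg.encoder_channels
        self.pool = MaxPool2d(2)
        self.stages = ModuleList(
            LFE(channels[i], channels[i + 1], use_ccm=not cfg.no_ccm)
            for i in range(4))

    def forward(self, x: Tensor) -> list[Tensor]:
        """Return the four pyramid levels, shallow (1/2) to deep (1/16)."""
        b, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels}-channel input, got {c}")
        if h % 16 or w % 16:
            raise ValueError(f"input spatial dims ({h},{w}) must be divisible by 16")
        feats = []
        for stage in self.stages:
            x = stage(self.pool(x))
            feats.append(x)
        return feats
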