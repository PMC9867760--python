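"""CNN decoder with gated attention modules.

Four (bilinear ×2 upsample → LFE) stages mirror the encoder, consuming its
stage outputs as channel-concatenated skip connections at 1/8, 1/4 and 1/2
scale.  Two weighted squeeze-and-excitation (wSq) modules follow stages two
and three and one concurrent channel/spatial squeeze-and-excitation (SCSE)
module follows stage four; a final pointwise convolution emits the
single-channel candidate map.

Both attention modules implement y = x·gate_a(x) + x·gate_b(x):

* **wSq** — gate_a is a full-shape gate from a weighted average pooling
  (WAP: padded, size-preserving averaging whose denominator always counts
  padded zeros, down-weighting borders) followed by two pointwise
  convolutions and a sigmoid; gate_b is a single pointwise convolution to
  one channel plus sigmoid, broadcast across channels.
* **SCSE** — the standard concurrent pair: a channel gate from global
  average pooling through a bottleneck, and a spatial gate from a
  one-channel pointwise convolution.

The source description swaps the cSE/sSE labels relative to the usual
convention; the implementation is named by structure (pooling branch vs.
one-channel pointwise branch) rather than by label.
"""

from __future__ import annotations

from .blocks import LFE
from .config import PSNetConfig, WSqConfig
from .nn import (Conv2d, Module, ModuleList, Tensor, avg_pool2d, concat,
                 relu, resize_bilinear, sigmoid)

__all__ = ["WSq", "SCSE", "PSDecoder"]


class WSq(Module):
    """Weighted squeeze-and-excitation gate pair."""

    def __init__(self, channels: int, cfg: WSqConfig | None = None):
        super().__init__()
        cfg = cfg or WSqConfig()
        if channels < 2:
            raise ValueError("wSq needs >= 2 channels so the reduction keeps >= 1")
        reduced = channels // cfg.reduction
        if reduced < 1:
            raise ValueError(f"reduction {cfg.reduction} collapses {channels} "
                             "channels to zero")
        self.cfg = cfg
        self.pw_a1 = Conv2d(channels, reduced, 1)
        self.pw_a2 = Conv2d(reduced, channels, 1)
        self.pw_b = Conv2d(channels, 1, 1)

    def forward(self, x: Tensor) -> Tensor:
        c = self.cfg
        pooled = avg_pool2d(x, c.kernel, stride=c.stride, padding=c.padding)
        if pooled.shape[2:] != x.shape[2:]:
            pooled = resize_bilinear(pooled, x.shape[2:])
        gate_a = sigmoid(self.pw_a2(self.pw_a1(pooled)))
        gate_b = sigmoid(self.pw_b(x))  # (b,1,h,w), broadcast over channels
        return x * gate_a + x * gate_b


class SCSE(Module):
    """Concurrent channel + spatial squeeze-and-excitation (additive)."""

    def __init__(self, channels: int, reduction: int = 2):
        super().__init__()
        reduced = max(channels // reduction, 1)
        self.fc1 = Conv2d(channels, reduced, 1)
        self.fc2 = Conv2d(reduced, channels, 1)
        self.spatial = Conv2d(channels, 1, 1)

    def forward(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(2, 3), keepdims=True)
        channel_gate = sigmoid(self.fc2(relu(self.fc1(pooled))))
        spatial_gate = sigmoid(self.spatial(x))
        return x * channel_gate + x * spatial_gate


class PSDecoder(Module):
    def __init__(self, cfg: PSNetConfig):
        super().__init__()
        enc = cfg.encoder_channels           # (64, 128, 256, 512)
        dec = cfg.decoder_channels           # (256, 128, 64, 32)
        # skips, deep to shallow, for stages 1..3; stage 4 has no 1/1 skip
        skips = (enc[2], enc[1], enc[0], 0)
        ins = (enc[3],) + dec[:3]
        self.stages = ModuleList(
            LFE(ins[i] + skips[i], dec[i], use_ccm=not cfg.no_ccm)
            for i in range(4))
        self.attention = ModuleList([
            _NoAttention(),
            WSq(dec[1], cfg.wsq),
            WSq(dec[2], cfg.wsq),
            SCSE(dec[3]),
        ])
        self.final = Conv2d(dec[3], 1, 1)
        self.deep_channels = enc[3]

    def forward(self, pyramid: list[Tensor]) -> Tensor:
        """pyramid: encoder stage outputs, shallow (1/2) to deep (1/16)."""
        if len(pyramid) != 4:
            raise ValueError(f"expected a 4-level pyramid, got {len(pyramid)}")
        x = pyramid[-1]
        if x.shape[1] != self.deep_channels:
            raise ValueError(f"deepest pyramid level has {x.shape[1]} channels, "
                             f"configured {self.deep_channels}")
        skips = [pyramid[2], pyramid[1], pyramid[0], None]
        for stage, attn, skip in zip(self.stages, self.attention, skips):
            _, _, h, w = x.shape
            x = resize_bilinear(x, (h * 2, w * 2))
            if skip is not None:
                if skip.shape[2:] != x.shape[2:]:
                    raise ValueError(f"skip at {skip.shape[2:]} does not match "
                                     f"decoder stream at {x.shape[2:]}")
                x = concat([x, skip], axis=1)
            x = attn(stage(x))
        return self.final(x)


class _NoAttention(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x
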