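"""Convolutional primitives of the CNN branch.

Three composites recur throughout the network:

* **DWSC** — depthwise separable standard convolution: a per-channel spatial
  convolution followed by a pointwise (1x1) channel-mixing convolution, with
  batch normalization and an activation after the pointwise step.
* **CCM** — complex convolutional module: two groups of depthwise
  convolutions with growing receptive field.  Group one runs 1xk, kx1, kxk
  with k=3 at dilation 2; group two repeats with k=5 at dilation 3.  Batch
  normalization follows every convolution; one activation closes each group
  (PReLU after the k=3 group, ReLU6 after the k=5 group).
* **LFE** — local feature extraction: two DWSCs (the first carries the
  channel change) followed by a CCM.

All paddings are chosen as d·(k−1)/2 per convolved axis so spatial size is
preserved; an even effective kernel extent cannot be padded symmetrically and
is rejected at construction time.
"""

from __future__ import annotations

from .nn import (BatchNorm2d, Conv2d, Identity, Module, PReLU, ReLU6,
                 SiLU, Tensor)

__all__ = ["DepthwiseSeparableConv", "CCM", "LFE", "make_activation"]

_ACTIVATIONS = {"silu": SiLU, "prelu": PReLU, "relu6": ReLU6, "none": Identity}


def make_activation(name: str) -> Module:
    try:
        return _ACTIVATIONS[name]()
    except KeyError:
        raise ValueError(f"unknown activation {name!r}; "
                         f"choose from {sorted(_ACTIVATIONS)}") from None


class DepthwiseSeparableConv(Module):
    """Depthwise kxk convolution + pointwise channel mix (+ BN + activation)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3, *,
                 stride: int = 1, padding: int = 1, dilation: int = 1,
                 normalize: bool = True, activation: str = "silu"):
        super().__init__()
        self.depthwise = Conv2d(in_channels, in_channels, kernel, stride=stride,
                                padding=padding, dilation=dilation,
                                groups=in_channels, bias=False)
        self.pointwise = Conv2d(in_channels, out_channels, 1, bias=True)
        self.norm = BatchNorm2d(out_channels) if normalize else Identity()
        self.act = make_activation(activation)

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.norm(self.pointwise(self.depthwise(x))))


def _size_preserving_pad(k: int, d: int) -> int:
    extent = d * (k - 1)
    if extent % 2:
        raise ValueError(
            f"kernel {k} at dilation {d} has even effective extent {extent + 1}; "
            "symmetric size-preserving padding is impossible")
    return extent // 2


class _DepthwiseBN(Module):
    """One depthwise convolution (possibly asymmetric/dilated) + BN."""

    def __init__(self, channels: int, kernel: tuple[int, int], dilation: int):
        super().__init__()
        kh, kw = kernel
        pad = (_size_preserving_pad(kh, dilation), _size_preserving_pad(kw, dilation))
        self.conv = Conv2d(channels, channels, kernel, padding=pad,
                           dilation=dilation, groups=channels, bias=False)
        self.norm = BatchNorm2d(channels)

    def forward(self, x: Tensor) -> Tensor:
        return self.norm(self.conv(x))


class CCM(Module):
    """Two-pass depthwise asymmetric + dilated convolution stack.

    Channel count and spatial size are preserved.  The dilation widens the
    receptive field: a kxk depthwise layer at dilation d covers
    d·(k−1)+1 pixels per axis (13 for k=5, d=3).
    """

    def __init__(self, channels: int, kernels: tuple[int, int] = (3, 5),
                 dilations: tuple[int, int] = (2, 3)):
        super().__init__()
        k1, k2 = kernels
        d1, d2 = dilations
        self.conv1a = _DepthwiseBN(channels, (1, k1), d1)
        self.conv1b = _DepthwiseBN(channels, (k1, 1), d1)
        self.conv1c = _DepthwiseBN(channels, (k1, k1), d1)
        self.act1 = PReLU()
        self.conv2a = _DepthwiseBN(channels, (1, k2), d2)
        self.conv2b = _DepthwiseBN(channels, (k2, 1), d2)
        self.conv2c = _DepthwiseBN(channels, (k2, k2), d2)
        self.act2 = ReLU6()

    def forward(self, x: Tensor) -> Tensor:
        x = self.act1(self.conv1c(self.conv1b(self.conv1a(x))))
        return self.act2(self.conv2c(self.conv2b(self.conv2a(x))))


class LFE(Module):
    """Local feature extraction: dual DWSC then CCM.

    The first DWSC carries the channel change; the second preserves it.
    ``use_ccm=False`` replaces the CCM with identity (ablation switch).
    """

    def __init__(self, in_channels: int, out_channels: int, use_ccm: bool = True):
        super().__init__()
        self.dwsc1 = DepthwiseSeparableConv(in_channels, out_channels)
        self.dwsc2 = DepthwiseSeparableConv(out_channels, out_channels)
        self.ccm = CCM(out_channels) if use_ccm else Identity()

    def forward(self, x: Tensor) -> Tensor:
        return self.ccm(self.dwsc2(self.dwsc1(x)))
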