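"""Structured ops: convolution, pooling, bilinear resizing, normalization.

Convolutions are computed tap-by-tap: for each kernel offset ``(u, v)`` the
padded input is sliced at that offset and either scaled (depthwise) or mixed
through a channel matmul (dense / pointwise).  This keeps peak memory at one
feature map per tap instead of a full im2col buffer, and gives an exact,
easily-audited backward rule (the transposed scatter of the same slices).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from . import _kernels
from .tensor import Tensor, no_grad, sigmoid

__all__ = [
    "conv2d",
    "max_pool2d",
    "avg_pool2d",
    "resize_bilinear",
    "silu",
    "prelu",
    "layer_norm",
    "conv_out_size",
]


def _pair(v) -> tuple[int, int]:
    return tuple(v) if isinstance(v, (tuple, list)) else (int(v), int(v))


def conv_out_size(n: int, k: int, stride: int, pad: int, dilation: int) -> int:
    """Output length of a 1-D convolution axis."""
    return (n + 2 * pad - dilation * (k - 1) - 1) // stride + 1


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
           stride: int = 1, padding=0, dilation: int = 1, groups: int = 1) -> Tensor:
    """2-D cross-correlation over NCHW input.

    ``groups`` is either 1 (dense) or equal to the input channel count
    (depthwise, one filter per channel with weight shape (C, 1, kh, kw)).
    Dense kernels larger than 1x1 go through an im2col buffer and a single
    channel matmul; depthwise kernels use a tap-by-tap scaled accumulation.
    """
    x = x if isinstance(x, Tensor) else Tensor(x)
    b, c, h, w = x.shape
    out_c, wc, kh, kw = weight.shape
    ph, pw = _pair(padding)
    s, d = int(stride), int(dilation)
    depthwise = groups != 1
    if depthwise:
        if groups != c or out_c != c or wc != 1:
            raise ValueError(
                f"depthwise conv needs groups == in channels == out channels; "
                f"got groups={groups}, input channels={c}, weight shape {weight.shape}")
    elif wc != c:
        raise ValueError(
            f"channel mismatch: input has {c} channels but weight {weight.shape} "
            f"expects {wc}")
    oh = conv_out_size(h, kh, s, ph, d)
    ow = conv_out_size(w, kw, s, pw, d)
    if oh < 1 or ow < 1:
        raise ValueError(f"convolution output would be empty: input {h}x{w}, "
                         f"kernel {kh}x{kw}, dilation {d}, padding {ph},{pw}")

    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    h_stop = (oh - 1) * s + 1
    w_stop = (ow - 1) * s + 1
    taps = [(u, v) for u in range(kh) for v in range(kw)]

    def tap_view(arr, u, v):
        return arr[:, :, u * d:u * d + h_stop:s, v * d:v * d + w_stop:s]

    cols = None
    if depthwise:
        out = _kernels.dw_forward(np.ascontiguousarray(xp), weight.data[:, 0],
                                  s, d, oh, ow)
    elif (kh, kw) == (1, 1):
        out = np.matmul(weight.data[:, :, 0, 0],
                        xp.reshape(b, c, oh * ow)).reshape(b, out_c, oh, ow)
    else:
        # im2col: (b, c·kh·kw, oh·ow), taps ordered row-major to match weight
        cols = np.empty((b, c * len(taps), oh * ow), dtype=x.data.dtype)
        for i, (u, v) in enumerate(taps):
            cols[:, i * c:(i + 1) * c] = tap_view(xp, u, v).reshape(b, c, -1)
        # W2[(u·kw+v)·c + ch, o] = weight[o, ch, u, v]
        wmat = weight.data.transpose(2, 3, 1, 0).reshape(len(taps) * c, out_c).T
        out = np.matmul(wmat, cols).reshape(b, out_c, oh, ow)
    if bias is not None:
        out = out + bias.data[None, :, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        g3 = g.reshape(b, out_c, oh * ow)
        if depthwise:
            gc = np.ascontiguousarray(g)
            if weight.requires_grad:
                gw = _kernels.dw_grad_w(np.ascontiguousarray(xp), gc, s, d, kh, kw)
                weight._accumulate(gw[:, None])
            if x.requires_grad:
                gxp = _kernels.dw_grad_x(gc, weight.data[:, 0], s, d,
                                         h + 2 * ph, w + 2 * pw)
                x._accumulate(gxp[:, :, ph:ph + h, pw:pw + w])
        elif (kh, kw) == (1, 1):
            if weight.requires_grad:
                gw = np.matmul(g3, xp.reshape(b, c, oh * ow).transpose(0, 2, 1)
                               ).sum(axis=0)
                weight._accumulate(gw.reshape(weight.data.shape))
            if x.requires_grad:
                gx = np.matmul(weight.data[:, :, 0, 0].T, g3).reshape(b, c, oh, ow)
                x._accumulate(gx)
        else:
            if weight.requires_grad:
                gw = np.matmul(g3, cols.transpose(0, 2, 1)).sum(axis=0)  # (o, c·k²)
                gw = gw.reshape(out_c, len(taps), c).transpose(0, 2, 1)
                weight._accumulate(gw.reshape(weight.data.shape))
            if x.requires_grad:
                wmat = weight.data.transpose(2, 3, 1, 0).reshape(len(taps) * c, out_c)
                gcols = np.matmul(wmat, g3)  # (b, k²·c, oh·ow)
                gxp = np.zeros((b, c, h + 2 * ph, w + 2 * pw), dtype=g.dtype)
                for i, (u, v) in enumerate(taps):
                    tap_view(gxp, u, v)[...] += \
                        gcols[:, i * c:(i + 1) * c].reshape(b, c, oh, ow)
                x._accumulate(gxp[:, :, ph:ph + h, pw:pw + w])

    return Tensor._make(out, parents, backward)


def max_pool2d(x: Tensor, kernel: int = 2) -> Tensor:
    """Non-overlapping max pooling (kernel == stride); dims must divide."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    b, c, h, w = x.shape
    k = int(kernel)
    if h % k or w % k:
        raise ValueError(f"max_pool2d: spatial dims ({h},{w}) not divisible by {k}")
    oh, ow = h // k, w // k
    windows = x.data.reshape(b, c, oh, k, ow, k).transpose(0, 1, 2, 4, 3, 5)
    flat = windows.reshape(b, c, oh, ow, k * k)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gw = np.zeros_like(flat)
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gx = gw.reshape(b, c, oh, ow, k, k).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h, w)
        x._accumulate(gx)

    return Tensor._make(out, (x,), backward)


def avg_pool2d(x: Tensor, kernel: int, *, stride: int = 1, padding: int = 0) -> Tensor:
    """Size-flexible average pooling whose denominator is always kernel².

    Zero padding is *included* in the average, so windows overlapping the
    border are down-weighted — this is the weighting used by the decoder's
    weighted-average-pooling gate.
    """
    x = x if isinstance(x, Tensor) else Tensor(x)
    c = x.shape[1]
    k = int(kernel)
    w = Tensor(np.full((c, 1, k, k), 1.0 / (k * k), dtype=x.data.dtype))
    return conv2d(x, w, stride=stride, padding=padding, groups=c)


@lru_cache(maxsize=64)
def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic 1-D linear interpolation matrix (half-pixel centers)."""
    A = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    src = np.clip((np.arange(n_out) + 0.5) * scale - 0.5, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = (src - i0).astype(np.float32)
    rows = np.arange(n_out)
    np.add.at(A, (rows, i0), 1.0 - w1)
    np.add.at(A, (rows, i1), w1)
    return A


def resize_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear resize of an NCHW map to ``size`` (half-pixel convention).

    Separable: y = A_h · x · A_wᵀ, so the backward pass is the exact
    transpose A_hᵀ · g · A_w.
    """
    x = x if isinstance(x, Tensor) else Tensor(x)
    b, c, h, w = x.shape
    h2, w2 = int(size[0]), int(size[1])
    if (h2, w2) == (h, w):
        return x
    Ah = _interp_matrix(h, h2)
    Aw = _interp_matrix(w, w2)
    out = np.matmul(np.matmul(Ah, x.data), Aw.T)

    def backward(g):
        x._accumulate(np.matmul(np.matmul(Ah.T, g), Aw))

    return Tensor._make(out, (x,), backward)


def silu(x: Tensor) -> Tensor:
    """x · σ(x) — the smooth rectifier used throughout the CNN branch."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    with no_grad():
        s = sigmoid(Tensor(x.data)).data

    def backward(g):
        x._accumulate(g * (s * (1.0 + x.data * (1.0 - s))))

    return Tensor._make(x.data * s, (x,), backward)


def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float
                     ) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Batch normalization over (N, H, W) per channel, with fused backward.

    Returns (output, batch mean (C,), biased batch variance (C,)) — the
    caller maintains running statistics from the returned moments.
    """
    x = x if isinstance(x, Tensor) else Tensor(x)
    axes = (0, 2, 3)
    m = x.data.mean(axis=axes, keepdims=True)
    xc = x.data - m
    v = (xc * xc).mean(axis=axes, keepdims=True)
    invstd = 1.0 / np.sqrt(v + eps)
    xn = xc * invstd
    ga = gamma.data.reshape(1, -1, 1, 1)
    out = xn * ga + beta.data.reshape(1, -1, 1, 1)

    def backward(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if gamma.requires_grad:
            gamma._accumulate((g * xn).sum(axis=axes))
        if x.requires_grad:
            gxn = g * ga
            mean_g = gxn.mean(axis=axes, keepdims=True)
            mean_gx = (gxn * xn).mean(axis=axes, keepdims=True)
            x._accumulate(invstd * (gxn - mean_g - xn * mean_gx))

    t = Tensor._make(out, (x, gamma, beta), backward)
    return t, m.reshape(-1), v.reshape(-1)


def prelu(x: Tensor, slope: Tensor) -> Tensor:
    """max(0,x) + slope·min(0,x) with a learnable scalar slope."""
    from .tensor import relu
    return relu(x) - slope * relu(-x)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Normalization over the last axis (token features)."""
    m = x.mean(axis=-1, keepdims=True)
    xc = x - m
    v = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / (v + eps).sqrt() * gamma + beta
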