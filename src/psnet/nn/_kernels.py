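"""JIT-compiled inner loops for depthwise convolution.

Depthwise convolutions touch every pixel k² times with only a scalar
multiply per tap, so they are loop-overhead-bound in pure NumPy; these
kernels do the scalar loops in compiled code.  Weights are passed as
(C, kh, kw); inputs are the already-padded NCHW array.
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange

__all__ = ["dw_forward", "dw_grad_w", "dw_grad_x"]


@njit(cache=True, fastmath=True, parallel=True)
def dw_forward(xp, w, s, d, oh, ow):
    b, c, _, _ = xp.shape
    kh, kw = w.shape[1], w.shape[2]
    out = np.zeros((b, c, oh, ow), dtype=xp.dtype)
    for bc in prange(b * c):
        bi = bc // c
        ci = bc % c
        for u in range(kh):
            for v in range(kw):
                wv = w[ci, u, v]
                for i in range(oh):
                    io = i * s + u * d
                    for j in range(ow):
                        out[bi, ci, i, j] += wv * xp[bi, ci, io, j * s + v * d]
    return out


@njit(cache=True, fastmath=True, parallel=True)
def dw_grad_w(xp, g, s, d, kh, kw):
    b, c, _, _ = xp.shape
    _, _, oh, ow = g.shape
    gw = np.zeros((c, kh, kw), dtype=g.dtype)
    for ci in prange(c):
        for u in range(kh):
            for v in range(kw):
                acc = g[0, 0, 0, 0] * 0  # dtype-typed zero
                for bi in range(b):
                    for i in range(oh):
                        io = i * s + u * d
                        for j in range(ow):
                            acc += g[bi, ci, i, j] * xp[bi, ci, io, j * s + v * d]
                gw[ci, u, v] = acc
    return gw


@njit(cache=True, fastmath=True, parallel=True)
def dw_grad_x(g, w, s, d, hp, wp):
    b, c, oh, ow = g.shape
    kh, kw = w.shape[1], w.shape[2]
    gxp = np.zeros((b, c, hp, wp), dtype=g.dtype)
    for bc in prange(b * c):
        bi = bc // c
        ci = bc % c
        for u in range(kh):
            for v in range(kw):
                wv = w[ci, u, v]
                for i in range(oh):
                    io = i * s + u * d
                    for j in range(ow):
                        gxp[bi, ci, io, j * s + v * d] += wv * g[bi, ci, i, j]
    return gxp
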