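"""Transformer branch: patch embedding + repeated self-attention blocks.

The encoder follows the plain vision-transformer recipe: the image is cut
into non-overlapping PxP patches, each flattened and linearly embedded;
learned positional embeddings are added; L pre-norm blocks of multi-headed
self-attention and an MLP follow; a final layer norm closes the stack.  No
class token is kept — the downstream partial decoder consumes exactly the
N = (H/P)·(W/P) patch tokens.

A checkpoint loader supports transferring pretrained weights, bicubically
interpolating the positional-embedding grid when the source and target
resolutions differ.  The tensor-name table is simply this module's own
``state_dict`` names (documented in the README).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .config import ViTConfig
from .nn import (LayerNorm, Linear, Module, ModuleList, Tensor, matmul,
                 sigmoid, softmax)

__all__ = ["patchify", "inverse_patchify", "TransformerBlock", "ViTEncoder",
           "LoadReport", "load_pretrained", "CheckpointError"]


def patchify(image: Tensor, patch_size: int) -> Tensor:
    """Rearrange (b,c,H,W) into (b, N, c·P²) row-major patch vectors."""
    image = image if isinstance(image, Tensor) else Tensor(image)
    b, c, h, w = image.shape
    p = patch_size
    if h % p or w % p:
        raise ValueError(f"spatial dims ({h},{w}) not divisible by patch size {p}")
    gh, gw = h // p, w // p
    x = image.reshape(b, c, gh, p, gw, p)
    x = x.transpose(0, 2, 4, 1, 3, 5)  # (b, gh, gw, c, p, p)
    return x.reshape(b, gh * gw, c * p * p)


def inverse_patchify(tokens: Tensor, patch_size: int, height: int, width: int,
                     channels: int = 3) -> Tensor:
    """Exact inverse of :func:`patchify` (round-trips bit-for-bit)."""
    tokens = tokens if isinstance(tokens, Tensor) else Tensor(tokens)
    b, n, d = tokens.shape
    p = patch_size
    gh, gw = height // p, width // p
    x = tokens.reshape(b, gh, gw, channels, p, p)
    x = x.transpose(0, 3, 1, 4, 2, 5)
    return x.reshape(b, channels, height, width)


def _gelu(x: Tensor) -> Tensor:
    # tanh-form Gaussian error linear unit, composed from the sigmoid op:
    # tanh(z) = 2·sigmoid(2z) − 1.
    z = math.sqrt(2.0 / math.pi) * (x + 0.044715 * x * x * x)
    tanh = 2.0 * sigmoid(2.0 * z) - 1.0
    return 0.5 * x * (1.0 + tanh)


class Attention(Module):
    """Multi-headed scaled dot-product self-attention."""

    def __init__(self, dim: int, num_heads: int):
        super().__init__()
        if dim % num_heads:
            raise ValueError(f"dim {dim} not divisible by heads {num_heads}")
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.scale = self.head_dim ** -0.5
        self.q = Linear(dim, dim)
        self.k = Linear(dim, dim)
        self.v = Linear(dim, dim)
        self.proj = Linear(dim, dim)
        self.store_attn = False
        self.attn: np.ndarray | None = None  # (b, heads, N, N) when stored

    def _split(self, x: Tensor, b: int, n: int) -> Tensor:
        return x.reshape(b, n, self.num_heads, self.head_dim).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        b, n, d = x.shape
        q = self._split(self.q(x), b, n)
        k = self._split(self.k(x), b, n)
        v = self._split(self.v(x), b, n)
        scores = matmul(q, k.transpose(0, 1, 3, 2)) * self.scale
        weights = softmax(scores, axis=-1)
        if self.store_attn:
            self.attn = weights.data.copy()
        out = matmul(weights, v)  # (b, heads, n, head_dim)
        out = out.transpose(0, 2, 1, 3).reshape(b, n, d)
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-norm residual block: x + MSA(LN(x)), then x + MLP(LN(x))."""

    def __init__(self, dim: int, num_heads: int, mlp_ratio: float = 4.0):
        super().__init__()
        hidden = int(dim * mlp_ratio)
        self.norm1 = LayerNorm(dim)
        self.attn = Attention(dim, num_heads)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, hidden)
        self.fc2 = Linear(hidden, dim)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(_gelu(self.fc1(self.norm2(x))))


class ViTEncoder(Module):
    """Patch embedding + L transformer blocks + final layer norm."""

    def __init__(self, cfg: ViTConfig, image_size: int):
        super().__init__()
        from .nn import Parameter
        if image_size % cfg.patch_size:
            raise ValueError(f"image size {image_size} not divisible by "
                             f"patch size {cfg.patch_size}")
        self.cfg = cfg
        self.image_size = image_size
        self.grid = image_size // cfg.patch_size
        self.num_tokens = self.grid ** 2
        self.embed = Linear(3 * cfg.patch_size ** 2, cfg.embed_dim)
        self.pos_embed = Parameter(
            0.02 * np.random.default_rng(0).standard_normal(
                (1, self.num_tokens, cfg.embed_dim)).astype(np.float32))
        self.blocks = ModuleList(
            TransformerBlock(cfg.embed_dim, cfg.num_heads, cfg.mlp_ratio)
            for _ in range(cfg.depth))
        self.norm = LayerNorm(cfg.embed_dim)

    def patchify_embed(self, image: Tensor) -> Tensor:
        tokens = self.embed(patchify(image, self.cfg.patch_size))
        return tokens + self.pos_embed

    def forward(self, image: Tensor) -> Tensor:
        x = self.patchify_embed(image)
        for block in self.blocks:
            x = block(x)
        return self.norm(x)


# -- pretrained-weight transfer ------------------------------------------------

class CheckpointError(RuntimeError):
    pass


@dataclass
class LoadReport:
    """Outcome of a checkpoint transfer: every tensor is accounted for."""

    loaded: list[str] = field(default_factory=list)
    missing: list[str] = field(default_factory=list)   # in model, not in checkpoint
    unused: list[str] = field(default_factory=list)    # in checkpoint, not in model
    resized: list[str] = field(default_factory=list)   # positional grids interpolated

    def summary(self) -> str:
        return (f"loaded {len(self.loaded)} tensors, {len(self.missing)} missing, "
                f"{len(self.unused)} unused, {len(self.resized)} resized")


def _interpolate_pos_embed(src: np.ndarray, num_tokens: int) -> np.ndarray:
    """Bicubically resample a (1, N_src, d) positional grid to num_tokens."""
    _, n_src, dim = src.shape
    g_src = int(round(math.sqrt(n_src)))
    g_dst = int(round(math.sqrt(num_tokens)))
    if g_src * g_src != n_src or g_dst * g_dst != num_tokens:
        raise CheckpointError(
            f"positional grids must be square: {n_src} -> {num_tokens} tokens")
    grid = src.reshape(g_src, g_src, dim)
    zoom = (g_dst / g_src, g_dst / g_src, 1)
    out = ndimage.zoom(grid, zoom, order=3, mode="nearest")
    return out.reshape(1, g_dst * g_dst, dim).astype(src.dtype)


def load_pretrained(model: ViTEncoder, checkpoint) -> LoadReport:
    """Assign checkpoint tensors onto ``model`` by name.

    ``checkpoint`` is a mapping name → array or a path to an ``.npz`` file
    holding one.  Positional embeddings whose grid size differs from the
    model's are bicubically interpolated; every other shape mismatch leaves
    the tensor unloaded and reported in ``missing``.
    """
    if isinstance(checkpoint, (str, Path)):
        try:
            with np.load(checkpoint) as npz:
                checkpoint = {k: npz[k] for k in npz.files}
        except Exception as exc:
            raise CheckpointError(f"cannot read checkpoint {checkpoint}: {exc}") from exc
    state = model.state_dict()
    report = LoadReport()
    new_state = {}
    for name, value in state.items():
        if name not in checkpoint:
            report.missing.append(name)
            continue
        src = np.asarray(checkpoint[name])
        if name == "pos_embed" and src.shape != value.shape:
            try:
                src = _interpolate_pos_embed(src, model.num_tokens)
            except CheckpointError:
                report.missing.append(name)
                continue
            report.resized.append(name)
        if src.shape != value.shape:
            report.missing.append(name)
            continue
        new_state[name] = src
        report.loaded.append(name)
    report.unused = sorted(set(checkpoint) - set(report.loaded))
    merged = dict(state)
    merged.update(new_state)
    model.load_state_dict(merged)
    return report
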