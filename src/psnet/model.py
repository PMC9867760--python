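"""Full network assembly, deep-supervision averaging, loss and metrics.

The forward pass produces up to six full-resolution pre-activation candidate
maps — transformer stream (x^T), CNN stream (x^C) and four merge streams
(x^{1/16} … x^{1/2}) — whose elementwise mean x̄ feeds a single sigmoid.
Training minimizes 1 − softIoU(σ(x̄), y); under ablation the mean
renormalizes over the streams that remain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import PSNetConfig
from .merge import MergeModule
from .nn import Conv2d, Module, ModuleList, Tensor, concat, resize_bilinear, sigmoid
from .ps_decoder import PSDecoder
from .ps_encoder import PSEncoder
from .transformer_decoder import EnhancedDecoder, PartialDecoder
from .vit import ViTEncoder

__all__ = ["PSNet", "CandidateMaps", "iou_loss", "soft_iou", "dice_iou",
           "VARIANTS", "build_variant", "save_checkpoint", "load_checkpoint"]

VARIANTS = ("full", "no_transformer", "no_dual_decoder", "no_merge",
            "no_ps_encoder", "no_ccm")

MERGE_SCALES = (16, 8, 4, 2)


@dataclass
class CandidateMaps:
    """The candidate streams of one forward pass and their mean."""

    streams: dict[str, Tensor]   # name -> (b,1,H,W) pre-activation map
    mean: Tensor                 # elementwise mean over present streams

    def __len__(self) -> int:
        return len(self.streams)

    def probability(self) -> Tensor:
        """σ(x̄): the final segmentation probability map."""
        return sigmoid(self.mean)

    def prediction(self, threshold: float = 0.5) -> np.ndarray:
        return (self.probability().data > threshold).astype(np.uint8)


class PSNet(Module):
    """Dual encoder-decoder polyp segmentation network."""

    def __init__(self, cfg: PSNetConfig):
        super().__init__()
        self.cfg = cfg
        has_cnn = not cfg.no_ps_encoder
        has_vit = not cfg.no_transformer
        if not (has_cnn or has_vit):
            raise ValueError("cannot ablate both encoder branches at once")
        if has_cnn:
            self.ps_encoder = PSEncoder(cfg)
        if has_vit:
            self.vit = ViTEncoder(cfg.vit, cfg.image_size)
            self.partial_decoder = PartialDecoder(cfg.vit.embed_dim, cfg.mu)
        if cfg.no_dual_decoder:
            # replacement head: concat deepest features -> pointwise -> upsample
            fuse_in = (cfg.encoder_channels[-1] if has_cnn else 0) + \
                      (cfg.mu if has_vit else 0)
            self.fuse = Conv2d(fuse_in, 1, 1)
        else:
            if has_cnn:
                self.ps_decoder = PSDecoder(cfg)
            if has_vit:
                self.enhanced_decoder = EnhancedDecoder(cfg)
            if not cfg.no_merge:
                stage_of_scale = {16: 3, 8: 2, 4: 1, 2: 0}
                self.merges = ModuleList(
                    MergeModule(
                        cfg, s,
                        ps_channels=(cfg.encoder_channels[stage_of_scale[s]]
                                     if has_cnn else None),
                        use_grid=has_vit)
                    for s in MERGE_SCALES)

    # -- forward -------------------------------------------------------------
    def forward(self, image: Tensor) -> CandidateMaps:
        image = image if isinstance(image, Tensor) else Tensor(image)
        cfg = self.cfg
        b, c, h, w = image.shape
        if h != cfg.image_size or w != cfg.image_size:
            raise ValueError(f"input is {h}x{w} but the model is configured for "
                             f"{cfg.image_size}x{cfg.image_size}")
        pyramid = self.ps_encoder(image) if not cfg.no_ps_encoder else None
        grid = None
        if not cfg.no_transformer:
            grid = self.partial_decoder(self.vit(image))

        streams: dict[str, Tensor] = {}
        if cfg.no_dual_decoder:
            parts = []
            if pyramid is not None:
                parts.append(pyramid[-1])
            if grid is not None:
                parts.append(grid)
            fused = self.fuse(parts[0] if len(parts) == 1 else concat(parts, axis=1))
            streams["fused"] = resize_bilinear(fused, (h, w))
        else:
            if grid is not None:
                streams["transformer"] = self.enhanced_decoder(grid)
            if pyramid is not None:
                streams["cnn"] = self.ps_decoder(pyramid)
            if not cfg.no_merge:
                for merge, s in zip(self.merges, MERGE_SCALES):
                    feat = None
                    if pyramid is not None:
                        feat = pyramid[{16: 3, 8: 2, 4: 1, 2: 0}[s]]
                    streams[f"merge_1/{s}"] = merge(feat, grid)

        for name, stream in streams.items():
            if stream.shape != (b, 1, h, w):
                raise RuntimeError(f"stream {name!r} has shape {stream.shape}, "
                                   f"expected {(b, 1, h, w)}")
        mean = average_streams(list(streams.values()))
        return CandidateMaps(streams=streams, mean=mean)

    def parameter_count(self) -> int:
        return self.num_parameters()


def average_streams(streams: list[Tensor]) -> Tensor:
    """Elementwise mean over the present candidate streams."""
    if not streams:
        raise ValueError("no candidate streams to average")
    total = streams[0]
    for s in streams[1:]:
        total = total + s
    return total * (1.0 / len(streams))


# -- loss and metrics ----------------------------------------------------------

def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    vals = np.unique(y)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"mask must be binary (0/1); found values {vals[:5]}")
    return y.astype(np.float32)


def soft_iou(logits: Tensor, target: np.ndarray, eps: float = 1e-6) -> Tensor:
    """Soft intersection-over-union of σ(logits) against a binary mask."""
    y = _check_binary(target)
    if logits.shape != y.shape:
        raise ValueError(f"shape mismatch: logits {logits.shape} vs mask {y.shape}")
    p = sigmoid(logits)
    inter = (p * Tensor(y)).sum()
    union = p.sum() + float(y.sum()) - inter
    return (inter + eps) / (union + eps)


def iou_loss(mean_logits: Tensor, target: np.ndarray, eps: float = 1e-6) -> Tensor:
    """1 − softIoU: the training objective, differentiable in the logits.

    With an empty target and strongly negative logits the ε-regularized
    ratio tends to 1, so the loss tends to 0 (empty-vs-empty convention).
    """
    return 1.0 - soft_iou(mean_logits, target, eps)


def dice_iou(pred: np.ndarray, target: np.ndarray) -> tuple[float, float]:
    """Hard Dice and IoU of two binary masks; empty vs empty scores (1, 1)."""
    p = _check_binary(pred)
    g = _check_binary(target)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    inter = float((p * g).sum())
    ps, gs = float(p.sum()), float(g.sum())
    if ps == 0 and gs == 0:
        return 1.0, 1.0
    dice = 2.0 * inter / (ps + gs)
    iou = inter / (ps + gs - inter)
    return dice, iou


# -- variants ------------------------------------------------------------------

def build_variant(cfg: PSNetConfig, variant: str = "full") -> PSNet:
    """Instantiate an ablation variant by name (see :data:`VARIANTS`)."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    d = cfg.to_dict()
    for flag in ("no_transformer", "no_dual_decoder", "no_merge",
                 "no_ps_encoder", "no_ccm"):
        d[flag] = False
    if variant != "full":
        d[variant] = True
    return PSNet(PSNetConfig.from_dict(d))


# -- checkpointing -------------------------------------------------------------

def save_checkpoint(model: PSNet, path: str | Path) -> None:
    """Serialize parameters + buffers + config to a single ``.npz`` file."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.cfg.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path: str | Path) -> PSNet:
    with np.load(path) as npz:
        state = {k: npz[k] for k in npz.files}
    cfg = PSNetConfig.from_dict(json.loads(state.pop("__config__").tobytes().decode()))
    model = PSNet(cfg)
    model.load_state_dict(state)
    return model
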