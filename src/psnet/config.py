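"""Configuration tree for the network, training and data pipeline.

Everything the architecture leaves tunable lives here: image geometry,
channel schedules, the transformer variant, the number of tissue logits μ,
the weighted-average-pooling gate geometry, and the ablation switches.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["ViTConfig", "WSqConfig", "PSNetConfig", "TrainConfig", "SynthConfig"]


@dataclass
class ViTConfig:
    """Transformer-encoder hyperparameters (ViT-B/16 defaults)."""

    patch_size: int = 16
    depth: int = 12
    embed_dim: int = 768
    num_heads: int = 12
    mlp_ratio: float = 4.0
    checkpoint: str | None = None

    def __post_init__(self):
        if self.embed_dim % self.num_heads:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by heads {self.num_heads}")

    @classmethod
    def tiny(cls) -> "ViTConfig":
        """A 2-layer, 64-dim variant for fast CPU tests."""
        return cls(patch_size=16, depth=2, embed_dim=64, num_heads=4, mlp_ratio=2.0)


@dataclass
class WSqConfig:
    """Geometry of the weighted-average-pooling (WAP) gate.

    Padding is included in the averaging denominator, so border windows are
    down-weighted — that inclusion is the "weighting".
    """

    kernel: int = 7
    stride: int = 1
    padding: int = 3
    reduction: int = 2

    def __post_init__(self):
        if self.kernel < 1:
            raise ValueError("WAP kernel must be >= 1")
        if self.padding >= self.kernel:
            raise ValueError("WAP padding must be smaller than the kernel")
        if self.reduction < 1:
            raise ValueError("channel reduction ratio must be >= 1")


@dataclass
class PSNetConfig:
    """Full hyperparameter tree of the dual encoder-decoder."""

    image_size: int = 512
    in_channels: int = 3
    encoder_channels: tuple[int, ...] = (64, 128, 256, 512)
    decoder_channels: tuple[int, ...] = (256, 128, 64, 32)
    mu: int = 64
    merge_channels: int = 64
    vit: ViTConfig = field(default_factory=ViTConfig)
    wsq: WSqConfig = field(default_factory=WSqConfig)
    enhanced_up_factors: tuple[int, int] = (4, 4)
    # ablation switches
    no_transformer: bool = False
    no_dual_decoder: bool = False
    no_merge: bool = False
    no_ps_encoder: bool = False
    no_ccm: bool = False
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.vit, dict):
            self.vit = ViTConfig(**self.vit)
        if isinstance(self.wsq, dict):
            self.wsq = WSqConfig(**self.wsq)
        self.encoder_channels = tuple(self.encoder_channels)
        self.decoder_channels = tuple(self.decoder_channels)
        self.enhanced_up_factors = tuple(self.enhanced_up_factors)
        if self.mu < 1:
            raise ValueError("mu must be >= 1")
        if self.image_size % 16:
            raise ValueError(f"image_size {self.image_size} not divisible by 16")
        if self.image_size % self.vit.patch_size:
            raise ValueError(f"image_size {self.image_size} not divisible by "
                             f"patch size {self.vit.patch_size}")
        if len(self.encoder_channels) != 4 or len(self.decoder_channels) != 4:
            raise ValueError("encoder/decoder channel schedules must have 4 stages")

    @classmethod
    def tiny(cls, **overrides) -> "PSNetConfig":
        """64x64 input with a tiny transformer; full channel schedule."""
        kw = dict(image_size=64, vit=ViTConfig.tiny())
        kw.update(overrides)
        return cls(**kw)

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PSNetConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PSNetConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class TrainConfig:
    """Optimization recipe: Adam with a warm-up polynomial schedule."""

    epochs: int = 400
    batch_size: int = 16
    initial_lr: float = 2.1052e-5
    peak_lr: float = 2.1052e-4  # ramp target; 10x the initial rate
    warmup_epochs: int = 20
    poly_power: float = 0.98
    seed: int = 0
    eval_interval: int = 1
    max_steps: int | None = None
    checkpoint_dir: str | None = None

    def __post_init__(self):
        if not (0 < self.warmup_epochs < self.epochs):
            raise ValueError("need 0 < warmup_epochs < epochs")
        if self.initial_lr <= 0 or self.peak_lr <= 0:
            raise ValueError("learning rates must be positive")


@dataclass
class SynthConfig:
    """Parameters of the synthetic colonoscopy-frame generator."""

    n_images: int = 16
    image_size: int = 64
    polyps_min: int = 0
    polyps_max: int = 3
    radius_min: float = 0.08
    radius_max: float = 0.2
    boundary_harmonics: int = 4
    boundary_amplitude: float = 0.15
    contrast: float = 0.25
    texture_sd: float = 0.04
    vignette_strength: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.radius_min <= self.radius_max < 0.5):
            raise ValueError("radius fractions must satisfy 0 < min <= max < 0.5")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.polyps_min < 0 or self.polyps_max < self.polyps_min:
            raise ValueError("invalid polyp count range")
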