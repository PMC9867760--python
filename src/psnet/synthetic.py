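"""Seeded generator of colonoscopy-like frames with exact ground-truth masks.

Each frame is a mucosa-toned textured background under a circular dark
vignette (the round field of view of an endoscope), containing between
``polyps_min`` and ``polyps_max`` smooth blob-shaped polyp regions.  Polyp
boundaries are deformed ellipses: a circle perturbed radially by a low-order
Fourier series, rotated and anisotropically scaled, which yields the smooth,
irregular outlines typical of real polyps.  Polyp regions are brightened and
reddened relative to the surrounding mucosa by at least the configured
contrast, carry their own texture, and receive a soft specular highlight.
The mask is the exact rasterized polyp support.

Everything is driven by one seeded generator, so identical configurations
produce byte-identical PNG files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .config import SynthConfig
from .data import DatasetManifest, SampleRecord

__all__ = ["generate", "render_frame"]


def _smooth_noise(rng: np.random.Generator, size: int, sigma: float,
                  amplitude: float) -> np.ndarray:
    noise = rng.standard_normal((size, size))
    smooth = ndimage.gaussian_filter(noise, sigma)
    scale = smooth.std()
    return amplitude * smooth / (scale if scale > 0 else 1.0)


def _polyp_mask(size: int, center: tuple[float, float], radii: tuple[float, float],
                angle: float, harmonics: np.ndarray, phases: np.ndarray) -> np.ndarray:
    """Rasterize one radially-perturbed rotated ellipse; True inside."""
    yy, xx = np.mgrid[0:size, 0:size]
    dy = (yy - center[0]) / size
    dx = (xx - center[1]) / size
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * dx + sa * dy) / radii[0]
    v = (-sa * dx + ca * dy) / radii[1]
    rho = np.sqrt(u * u + v * v)
    theta = np.arctan2(v, u)
    boundary = 1.0
    for k, (a, phi) in enumerate(zip(harmonics, phases), start=2):
        boundary = boundary + a * np.cos(k * theta + phi)
    return rho <= boundary


def render_frame(cfg: SynthConfig, rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Render one (image uint8 HxWx3, mask uint8 HxW in {0,255}) pair."""
    s = cfg.image_size
    yy, xx = np.mgrid[0:s, 0:s]
    r_norm = np.sqrt(((yy - s / 2) ** 2 + (xx - s / 2) ** 2)) / (s / 2)

    # mucosa-toned background with low-frequency texture
    base = np.array([0.60, 0.40, 0.36]) + rng.uniform(-0.05, 0.05, size=3)
    img = np.empty((s, s, 3))
    shading = _smooth_noise(rng, s, sigma=s / 8, amplitude=0.06)
    for ch in range(3):
        img[..., ch] = base[ch] + shading + \
            _smooth_noise(rng, s, sigma=s / 16, amplitude=0.03)

    # polyps
    mask = np.zeros((s, s), dtype=bool)
    n_polyps = int(rng.integers(cfg.polyps_min, cfg.polyps_max + 1))
    for _ in range(n_polyps):
        r0 = rng.uniform(cfg.radius_min, cfg.radius_max)
        aspect = rng.uniform(0.7, 1.0)
        center = rng.uniform(0.25 * s, 0.75 * s, size=2)
        amps = cfg.boundary_amplitude * rng.uniform(-1, 1, cfg.boundary_harmonics) \
            / np.arange(1, cfg.boundary_harmonics + 1)
        phases = rng.uniform(0, 2 * np.pi, cfg.boundary_harmonics)
        region = _polyp_mask(s, tuple(center), (r0, r0 * aspect),
                             rng.uniform(0, np.pi), amps, phases)
        mask |= region
        # tone shift: brighter and redder than the local mucosa
        lift = rng.uniform(cfg.contrast + 0.03, cfg.contrast + 0.12)
        tone = np.array([lift * 1.1, lift * 1.0, lift * 1.0])
        texture = _smooth_noise(rng, s, sigma=s / 24, amplitude=0.03)
        for ch in range(3):
            img[..., ch] += region * (tone[ch] + texture)
        # soft specular highlight inside the polyp
        hy, hx = center + rng.uniform(-0.03 * s, 0.03 * s, size=2)
        blob = np.exp(-(((yy - hy) ** 2 + (xx - hx) ** 2) / (2 * (0.25 * r0 * s) ** 2)))
        img += (0.15 * blob * region)[..., None]

    # pixel noise and circular vignette
    img += rng.standard_normal((s, s, 3)) * cfg.texture_sd
    vignette = 1.0 - cfg.vignette_strength * np.clip(r_norm - 0.7, 0, None) / 0.3
    img *= np.clip(vignette, 1.0 - cfg.vignette_strength, 1.0)[..., None]

    img8 = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
    mask8 = (mask.astype(np.uint8)) * 255
    return img8, mask8


def generate(cfg: SynthConfig, out_dir: str | Path) -> DatasetManifest:
    """Write ``cfg.n_images`` PNG pairs + a manifest CSV under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    records = []
    for i in range(cfg.n_images):
        img8, mask8 = render_frame(cfg, rng)
        img_path = out / f"frame_{i:04d}.png"
        mask_path = out / f"frame_{i:04d}_mask.png"
        Image.fromarray(img8).save(img_path)
        Image.fromarray(mask8).save(mask_path)
        records.append(SampleRecord(str(img_path), str(mask_path), "synthetic"))
    manifest = DatasetManifest(records, protocol="synthetic", seed=cfg.seed)
    manifest.to_csv(out / "manifest.csv")
    return manifest
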