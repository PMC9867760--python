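"""Transfer transformer weights across input resolutions.

Saves a tiny transformer trained at 64x64 (4x4 token grid) and loads it
into a 128x128 model (8x8 grid): every tensor transfers by name and the
positional-embedding grid is bicubically interpolated.
"""

import tempfile
from pathlib import Path

import numpy as np

from psnet import ViTConfig, ViTEncoder, load_pretrained

cfg = ViTConfig.tiny()
src = ViTEncoder(cfg, image_size=64)
dst = ViTEncoder(cfg, image_size=128)

with tempfile.TemporaryDirectory() as td:
    ckpt = Path(td) / "vit.npz"
    np.savez(ckpt, **src.state_dict())
    report = load_pretrained(dst, ckpt)

print(report.summary())
print(f"  resized: {report.resized}")
print(f"  pos_embed now {dst.pos_embed.data.shape} "
      f"(source grid 4x4 -> target 8x8)")
# Expected: all tensors load, none missing/unused, pos_embed listed as
# resized with 64 tokens at the target resolution.
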