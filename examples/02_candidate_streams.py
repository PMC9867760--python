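"""One forward pass of the tiny configuration, stream by stream.

Builds the 64x64 test configuration (full channel schedule, 2-layer
transformer), runs one frame through it and prints the six candidate maps
that deep supervision averages into the final probability map.
"""

import numpy as np

from psnet import PSNet, PSNetConfig, init_weights
from psnet.nn import Tensor, no_grad

cfg = PSNetConfig.tiny()
model = PSNet(cfg)
init_weights(model, seed=0)
# training mode: batch statistics normalize each stage, so an untrained
# network still produces representative logit ranges (eval mode would use
# the never-updated running statistics instead)
model.train()
print(f"tiny model: {model.num_parameters():,} parameters")

x = np.random.default_rng(0).standard_normal((2, 3, 64, 64)).astype(np.float32)
with no_grad():
    out = model(Tensor(x))

for name, stream in out.streams.items():
    print(f"  {name:12s} {stream.shape}  logit range "
          f"[{stream.data.min():+.3f}, {stream.data.max():+.3f}]")
prob = out.probability().data
print(f"averaged map {out.mean.shape}; sigmoid output in "
      f"[{prob.min():.3f}, {prob.max():.3f}]")
# Six streams (transformer, CNN, four merge scales), all full resolution;
# their elementwise mean + one sigmoid is the segmentation probability.
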