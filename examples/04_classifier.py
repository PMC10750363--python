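"""Build the bottleneck-block 3D ResNet and inspect its shape ladder.

Uses a quarter-width variant for speed; the full-width network
(width_multiplier=1.0) has the identical topology with a 2048-long
pooled feature.
"""

import numpy as np

from gaitpipe.nn import (ArchitectureSpec, adapt_head, build_model, forward,
                         pooled_features)

spec = ArchitectureSpec(block_counts=(1, 1, 1, 1), width_multiplier=0.25,
                        input_side=64, seed=0)
model = build_model(spec)
x = np.random.default_rng(0).uniform(0, 1, (2, 3, 8, 64, 64)).astype(np.float32)

for stage in ("conv1", "pool1", "conv2_x", "conv3_x", "conv4_x", "conv5_x"):
    model.forward(x[:1], capture_stage=stage, keep_cache=False)
    print(f"{stage:8s} -> {model.captured.shape[1:]}")
# Spatial size halves at the stem, the pool and each later stage while
# the temporal size (8) is preserved throughout.

feats = pooled_features(model, x)
print(f"pooled feature: {feats.shape}  (2048 * width 0.25 = 512)")
for p in forward(model, x):
    print(f"scores {np.round(p.scores, 3)} -> predicted class {p.predicted}")

# Transfer-learning head swap: a 400-way head becomes 2-way, everything
# else bitwise untouched.
spec400 = ArchitectureSpec(block_counts=(1, 1, 1, 1), width_multiplier=0.25,
                           input_side=64, n_classes=400)
m400 = build_model(spec400)
adapt_head(m400, 2)
print(f"after head swap: {m400.forward(x, keep_cache=False).shape}")
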