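"""The enhanced channel attention math on a toy feature map.

Shows how the ECAM descriptor gates the average-pooled channel summary with
a sigmoid of the max-pooled summary, and how the resulting per-channel
weights recalibrate the feature map (all values strictly inside (0, 1)).
"""

import numpy as np

from encanet import (MLPWeights, apply_channel_attention, ecam_attention,
                     ecam_descriptor, global_average_pool, global_max_pool)

rng = np.random.default_rng(0)
x = rng.normal(size=(1, 8, 5, 5))          # one image, 8 channels, 5x5

z = global_average_pool(x)                 # per-channel mean
m = global_max_pool(x)                     # per-channel max
z_enh = ecam_descriptor(x)                 # sigmoid(max) * mean

print("channel   avg-pool   max-pool   enhanced descriptor")
for c in range(8):
    print(f"{c:>7} {z[0, c]:>10.4f} {m[0, c]:>10.4f} {z_enh[0, c]:>12.4f}")

w = MLPWeights.init(channels=8, reduction=2, rng=rng)
gate = ecam_attention(x, w)
out = apply_channel_attention(x, gate)
print("\nECAM gates (each in (0,1)):", np.round(gate[0], 4))
print("output-to-input energy ratio per channel:",
      np.round((out ** 2).sum(axis=(2, 3))[0] / (x ** 2).sum(axis=(2, 3))[0], 4))
print("A channel with a strong maximum keeps more of its signal; the MLP")
print("then mixes cross-channel context before the sigmoid squashes to (0,1).")
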