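"""Walk a forward pass through the residual-CBAM U-Net and print every
stage's feature-map shape.

At the published configuration (input 3x640x640, 64 base channels, 4
down-samplings) the encoder ends in a 1024x40x40 bottleneck and the
decoder restores a 3-channel 640x640 sigmoid probability map. Here the
desk-scale configuration (side 64, base 8) shows the same shape algebra:
channels double and the side halves at every stage.
"""

import numpy as np

from odcup import ModelConfig
from odcup.model import ResCbamUNet, as_batch
from odcup.nn import no_grad

cfg = ModelConfig.desk_scale(seed=0)
model = ResCbamUNet(cfg).eval()
img = np.random.default_rng(0).uniform(size=(64, 64, 3))

with no_grad():
    out, inter = model.forward_with_intermediates(as_batch(img))

print(f"config: side {cfg.input_side}, base {cfg.base_channels}, depth {cfg.depth}")
for name in [f"skip{i}" for i in range(cfg.depth)] + ["bottleneck",
                                                      "decoder_stage0", "output"]:
    t = inter[name]
    print(f"{name:>16}: {t.shape[1]:>4} channels, {t.shape[2]}x{t.shape[3]}")
print(f"output range: ({out.data.min():.3f}, {out.data.max():.3f})"
      "  <- independent per-channel sigmoid probabilities")
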