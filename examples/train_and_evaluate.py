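"""Train the scaled network on phantoms and evaluate held-out segmentation.

A short demonstration run (8 training phantoms, 160 optimizer steps) — the
loss falls and both structures emerge; the acceptance script runs the full
desk-scale protocol (32 phantoms, 300 steps). Expect one to two minutes on
a single CPU core.
"""

import numpy as np

from odcup import ModelConfig, PhantomSpec, TrainingConfig, evaluate, predict, train
from odcup.synthetic import generate_phantom, phantom_pairs
from odcup.training import preprocess_pair

side = 64
pairs = phantom_pairs(PhantomSpec(n_images=8, seed=1), side)
model_cfg = ModelConfig.desk_scale(seed=1)
train_cfg = TrainingConfig(epochs=80, batch_size=4, learning_rate=2e-2, seed=1)
model, log = train(model_cfg, train_cfg, pairs)
print(f"loss: {log.epoch_losses[0]:.3f} (epoch 1) -> "
      f"{log.epoch_losses[-1]:.3f} (epoch {len(log.epoch_losses)}), "
      f"{log.steps} optimizer steps")

held = PhantomSpec(n_images=4, seed=2)
reports = []
for i in range(held.n_images):
    img, _, disc_ann, cup_ann = generate_phantom(held, i)
    _, truth, _ = preprocess_pair(img, disc_ann, cup_ann, side)
    reports.append(evaluate(predict(model, img, 0.5), truth))

print("\nheld-out phantom metrics (overlap error = 1 - IoU; lower is better):")
print(f"  disc: E={np.mean([r.od_e for r in reports]):.3f}  "
      f"SEN={np.nanmean([r.od_sen for r in reports]):.3f}  "
      f"SPE={np.nanmean([r.od_spe for r in reports]):.3f}")
print(f"  cup : E={np.mean([r.cup_e for r in reports]):.3f}  "
      f"SEN={np.nanmean([r.cup_sen for r in reports]):.3f}  "
      f"SPE={np.nanmean([r.cup_spe for r in reports]):.3f}")
print(f"  vCDR mean abs error: "
      f"{np.nanmean([abs(r.vcdr_pred - r.vcdr_true) for r in reports]):.3f}")
# the disc (sharp bright boundary) is learned before the cup (interior,
# lower-contrast boundary) -- the same ordering clinical datasets show.
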