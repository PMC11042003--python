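"""Compute the vertical cup-to-disc ratio and pixel metrics from masks.

Shows the metric layer on its own: build nested label volumes from binary
masks, compare a 'prediction' against ground truth, and read off the
screening quantity (vCDR).
"""

import numpy as np

from odcup import build_label_volume, evaluate, vertical_cdr

yy, xx = np.mgrid[0:120, 0:120]

# ground truth: disc spanning rows 20..99 (height 80), cup rows 40..79 (40)
disc = (((xx - 60) / 42) ** 2 + ((yy - 60) / 40) ** 2 <= 1).astype(np.uint8)
cup = (((xx - 66) / 22) ** 2 + ((yy - 60) / 20) ** 2 <= 1).astype(np.uint8)
truth = build_label_volume(disc, cup)
print(f"truth vCDR = {vertical_cdr(truth):.3f}  "
      "(cup vertical extent / disc vertical extent)")

# a slightly-off prediction: both structures shifted and dilated a little
pdisc = (((xx - 62) / 44) ** 2 + ((yy - 61) / 41) ** 2 <= 1).astype(np.uint8)
pcup = (((xx - 64) / 24) ** 2 + ((yy - 62) / 22) ** 2 <= 1).astype(np.uint8)
pred = build_label_volume(pdisc, pcup)

rep = evaluate(pred, truth)
print(f"disc: overlap error {rep.od_e:.3f}, sensitivity {rep.od_sen:.3f}, "
      f"specificity {rep.od_spe:.3f}")
print(f"cup : overlap error {rep.cup_e:.3f}, sensitivity {rep.cup_sen:.3f}, "
      f"specificity {rep.cup_spe:.3f}")
print(f"predicted vCDR {rep.vcdr_pred:.3f} vs true {rep.vcdr_true:.3f}")
# overlap error is 1 - IoU; sensitivity/specificity are the pixelwise
# true-positive and true-negative rates for each structure.
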