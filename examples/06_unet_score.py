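"""U-net cancer-score map from rasterised cell features.

Per-cell features (6 marker means + density + area + axis lengths) are
painted into a 10-channel image; the U-net regresses the pixel-wise tumour
label, giving a score map in [0, 1].  Reduced desk-scale run (128-px slides,
200 epochs): about two minutes on one CPU.
"""

import numpy as np

import mifscore as m
from mifscore.models import UNetConfig, predict_unet, train_unet
from mifscore.pipeline import build_unet_slide, cell_accuracy, strong_separation_config

slides = [build_unet_slide(strong_separation_config(seed)) for seed in (11, 12, 13, 14)]
(r0, m0, _), (r1, m1, _), (r2, m2, _), (r3, _, test_table) = slides

model = train_unet([(r0, m0), (r1, m1)], [(r2, m2)], UNetConfig.desk_scale(), seed=0)
score = predict_unet(model, r3)

print(f"best validation MSE: {model.best_val_loss:.3f}")
print(f"score map range: [{score.values.min():.2f}, {score.values.max():.2f}]")
print(f"per-cell test accuracy: {cell_accuracy(score, test_table):.3f}")
# The score map is a [0,1] raster aligned to the slide; sampling it at each
# cell centroid and thresholding at 0.5 classifies cells as tumour/non-tumour.
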