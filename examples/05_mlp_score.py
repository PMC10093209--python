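"""Per-cell MLP cancer score (regression with batch-norm, Adam, MSE).

Three hidden layers of five times the input width, trained on the binary
region label; raw outputs are thresholded at the label midpoint.  Runs in
about half a minute.
"""

import numpy as np

import mifscore as m
from mifscore.models import MLPConfig, predict_mlp, train_mlp

informative = {f: 3.0 for f in ["area", "mean_DAPI", "density", "af_mean_CD3", "env_sd_area"]}
config = m.SimulationConfig(seed=8, n_cells_target=20_000, informative_features=informative)
table, labels = m.generate_feature_table(config)

model = train_mlp(
    table.X[:16_000], labels[:16_000], MLPConfig(epochs=40, subsample_stride=1), seed=0
)
scores = predict_mlp(model, table.X[16_000:])
rec = m.compute_metrics(scores > model.label_midpoint, labels[16_000:])
print(f"architecture: {model.n_features} -> "
      f"{model.config.hidden_width(model.n_features)} x {model.config.n_hidden_layers} -> 1")
print(f"held-out accuracy {rec.accuracy:.3f} "
      f"(sensitivity {rec.sensitivity:.3f}, specificity {rec.specificity:.3f})")
print(f"score distribution: mean {scores.mean():.2f}, "
      f"5-95% range [{np.percentile(scores, 5):.2f}, {np.percentile(scores, 95):.2f}]")
# Accuracy well above 0.9 shows the network learned the five planted features;
# the score spread shows it separates the classes rather than hedging at 0.5.
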