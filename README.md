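# mifscore

Cancer-score models for six-channel multiplex immunofluorescence (mIF) of
liver tissue.

Delineating the tumour area of a hepatocellular carcinoma (HCC) section is
the prerequisite for any quantitative analysis of its immune
microenvironment, but manual annotation is subjective and coarse.  Given
mIF slides stained with DAPI and five immune markers (CD3, CD4, CD8, PD-L1,
FoxP3) plus a pathologist's binary tumour mask, `mifscore` segments nuclei,
fuses tile-level detections from the scanner's overlapping grid, extracts a
68-dimensional feature vector per cell (intensity statistics, morphology,
positivity by the 2-SD rule, 300-px neighbourhood context), and compares
four models that turn those features into a **cancer score**
s ∈ [0, 1] per cell or pixel:

* **ICF** — the five features with the largest |Pearson r| against the mask
  label, scored as s = Σᵢ wᵢ vᵢ with wᵢ = |rᵢ| / Σⱼ|rⱼ|, vᵢ the
  percentile-normalised feature (0.01th percentile → 0, 99.9th → 1,
  clipped), inverted when rᵢ < 0;
* **MANOVA** — greedy forward selection minimising Wilks' Λ = det(W)/det(T),
  so each added feature must improve the joint separation; same scoring;
* **MLP** — a regression network 68 → 340 → 340 → 340 → 1 (batch-norm +
  ReLU, MSE loss, Adam at 1e-5, batch 128) on single cells;
* **U-net** — cell features rasterised into a 10-channel image (marker
  means, density, area, axis lengths) and regressed pixel-wise by a
  convolutional encoder-decoder (16 base maps, 3 strided down-samplings,
  LeakyReLU 0.2), which also sees the spatial context.

Scores are thresholded at 0.5 to classify tumour vs non-tumour, and
evaluated by leave-one-slide-out cross-validation (table models) or
(validation, test) slide pairs (U-net) with accuracy, sensitivity,
specificity and precision.  Because patient data of this kind are not
publicly deposited, the package includes a first-class synthetic-slide
generator with known ground truth — tumour masks, per-cell classes and
intensities, tile jitter — so every stage is testable end to end; see
`docs/methods.md` for what the synthetic data do and do not establish.

The neural models are small, deterministic NumPy implementations (explicit
forward/backward passes verified against numerical gradients), sized for
single-CPU experiments.

## Worked example

`examples/` contains one short script per capability.  For instance, the
linear models on a synthetic feature table with three planted informative
features (`python examples/04_linear_scores.py`):

```
ICF: selected ['area', 'mean_DAPI', 'density', 'mean25_CD3', 'pos_count_FoxP3']
       weights [0.326 0.325 0.325 0.013 0.011] (sum 1.000)
       held-out accuracy 0.925, sensitivity 0.995, specificity 0.858

MANOVA: selected ['area', 'density', 'mean_DAPI', 'pos_count_FoxP3', 'env_sd_mean25_FoxP3']
       weights [0.329 0.328 0.328 0.011 0.004] (sum 1.000)
       held-out accuracy 0.924, sensitivity 0.995, specificity 0.856
```

Both selectors find the three planted features (`area`, `mean_DAPI`,
`density`) and give them ~97% of the weight; the two noise features filling
the remaining slots get negligible weight, and held-out accuracy ~0.92
reflects the planted effect size.  The virtual-biopsy example
(`python examples/07_virtual_biopsies.py`) recovers a planted CD3 depletion
in tumour tissue:

```
sampled 20 ROIs (10 tumour)
CD3-positive cells: tumour 4.05 (0.79)%  non-tumour 7.83 (1.54)%  p = 0.0002
combination rows partition each class: tumour sums to 100.0%, non-tumour to 100.0%
```

i.e. the per-ROI tabulation reproduces the configured 3.85% / 8.08%
positive fractions within sampling error and flags the difference as
significant.  There is also a thin CLI covering the pipeline stages
(`mifscore simulate | fuse | extract | train | score | evaluate | ablate |
biopsies`), each reading one YAML run configuration.

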