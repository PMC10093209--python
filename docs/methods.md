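# Methods

`mifscore` implements an end-to-end analysis of six-channel multiplex
immunofluorescence (mIF) slides of liver tissue — DAPI plus CD3, CD4, CD8,
PD-L1 and FoxP3 — whose goal is a per-cell or per-pixel **cancer score**
in [0, 1] expressing how tumour-like the local tissue is, evaluated against
a pathologist's binary tumour mask.  This note records the models, the
conventions that were genuinely open, and what the synthetic data do and do
not establish.

## Imaging pipeline

**Tile alignment.**  Slide scanners acquire a grid of tiles with small
intentional overlaps; true tile positions deviate from the nominal grid by a
few pixels.  Alignment is detection-based: for each tile (row-major order,
tile (0,0) anchored at its nominal offset) a coarse-to-fine integer grid
search (strides 4, 2, 1 within ±`max_shift_px`, default 8) minimises the
summed nearest-neighbour distances between the tile's detections and those
of its already-anchored upper/left neighbours inside the overlap region.
Three numerical choices matter and are fixed:

* the query sets are frozen from the *nominal* geometry, so a candidate
  shift cannot lower its cost by pushing detections out of the overlap;
* candidate neighbour sets are padded by the search range, so a duplicate
  detection near the overlap edge matches its twin rather than an unrelated
  cell;
* nearest-neighbour distances are truncated at `max_shift_px + 2`, so a cell
  seen by only one tile contributes a constant instead of dragging the
  optimum.

A tile whose overlaps contain no detections cannot be aligned; it keeps its
nominal offset, is logged, and — importantly — is not used as an anchor for
later tiles, so its unknown jitter does not propagate down the scan order.

**Fusion.**  Detections mapped to slide coordinates are de-duplicated:
cross-tile pairs closer than `match_radius_px` (default 5 px ≈ 1.6 µm at
0.32 µm/px, below a typical nucleus radius) are grouped transitively and
each group keeps the detection with the largest nucleus area (ties: smaller
(tile row, col), then smaller label).  Fusion is idempotent.

**Segmentation.**  The bundled reference backend is Otsu thresholding of the
DAPI channel, a Euclidean distance transform, peak-seeded watershed and a
minimum-area filter.  It is adequate for well-separated synthetic nuclei and
keeps the package self-contained; heavier learned segmenters can be
registered behind the same label-image contract (`register_backend`).

## Per-cell features (68)

| group | count | content |
|---|---|---|
| intensity statistics | 18 | mean, mean25, pixel SD per channel |
| AF-corrected means | 5 | marker mean − per-slide baseline, clamped at 0 |
| morphology | 7 | area, centroid y/x, minor/major axis, eccentricity, circularity |
| density | 1 | neighbours within the radius |
| positive counts | 10 | per marker, raw and AF-corrected flags |
| environment SDs | 27 | local SD of the 18 intensity stats, 5 AF means, area, axes, density |

Conventions, fixed and asserted by tests: population SDs (`ddof=0`)
throughout; `mean25` is the mean of the brightest `ceil(0.25·area)` pixels
(so `mean25 ≥ mean` always); morphology uses ellipse-equivalent second
central moments with axis lengths floored at 1 px (a pixel has unit extent),
which keeps eccentricity in [0, 1) even for degenerate one-row segments;
circularity = 4πA/P².  The published feature list itemising all 68 entries
is not public; the registry above is a reconstruction constrained to the
documented families and the stated total of 68, and it is configuration-
driven so a corrected list can be swapped in without code changes.

**Positivity (2-SD rule).**  A cell is positive for a marker when its mean
intensity strictly exceeds the mean + 2 SD of all cells *of the same slide*
(staining intensity is slide-dependent, so pooling across slides would mix
thresholds).  Under a Gaussian null this calls the upper-tail fraction
P(Z > 2) ≈ 2.28%, which the tests verify at n = 100 000.

**Autofluorescence correction.**  The published correction procedure is not
described; the default reconstruction subtracts, per slide and marker, the
5th percentile of per-cell mean intensities (clamped at zero, so corrected
≤ raw).  The baseline estimator is a parameter; results that depend on it
should be interpreted accordingly.

**Neighbourhood features.**  Euclidean centroid distance, radius-inclusive,
default radius 300 px (~100 µm at 0.32 µm/px), computed exactly with a k-d
tree.  Density and positive counts exclude the focal cell; environment SDs
include it (a lone cell gets SD 0).  An O(n²) brute force is the test oracle.

## Scoring models

**Normalisation** (fitted on training slides only): `none`; `zscore`; and
`feature_specific` — percentile mapping of the 0.01th percentile to 0 and the
99.9th to 1 with clipping, leaving bounded features (eccentricity,
circularity) unchanged.  Degenerate features (zero SD or collapsed
percentiles) map to 0 with a warning.

**ICF.**  Pearson correlation of every feature with the binary label over
pooled training cells; the five largest |r| win (ties keep registry order).
The score is Σ wᵢvᵢ with wᵢ = |rᵢ|/Σ|rⱼ| (weights sum to 1), vᵢ the
percentile-normalised feature, inverted (1 − v) when rᵢ < 0; scores lie in
[0, 1] and are thresholded at 0.5 (the midpoint of the label codes).

**MANOVA.**  Greedy forward selection of five features minimising one-way
Wilks' Λ = det(W)/det(T) of the already-selected set plus the candidate, so
a near-duplicate of a selected feature adds no Λ reduction and an
independent weaker feature is preferred.  Singular candidates are skipped
with a warning.  Scoring is identical to ICF.

**MLP.**  Regression network: input width = registry length, three hidden
layers of 5× input width (340 for 68 features), each Dense layer followed by
batch normalisation and ReLU, single linear output, MSE loss against the
{0, 1} label, Adam at learning rate 1e-5, mini-batches of 128.  Defaults
follow the original schedule (every 10th cell, one epoch), which is
appropriate at millions of cells; at the 10⁴-cell scale of the synthetic
studies that schedule provides too few Adam steps at lr 1e-5 to converge, so
the bundled experiments train on all cells for 40 epochs (~5 000 steps) —
both knobs are config fields.  The implementation is a small in-package
NumPy layer stack (explicit forward/backward, verified against numerical
gradients), deterministic for a fixed seed.

**U-net.**  Per-cell features are rasterised into a 10-channel image (six
marker means, density, area, minor and major axis), each cell painted over
its nucleus footprint (or an equal-area disc), later cells winning
overlaps.  The network: 3×3 stride-1 convolutions, 16 feature maps at the
top level, three down-samplings by 4×4 stride-2 convolutions doubling the
maps, LeakyReLU (slope 0.2) after every convolution; the decoder — not
pinned down by the encoder description — is a standard mirror (nearest
up-sampling + 3×3 convolution, skip concatenation) with a 1×1 regression
head.  MSE loss on the pixel-wise label, Adam (learning rate 1e-3, a
standard default as none is prescribed), random square patches (256 px at
full scale; the desk preset uses 128 px and 200 epochs), batch 2,
checkpointing on minimum validation loss.  Two numerical choices stabilise
short training runs and are documented as this package's own: the regression
head is zero-initialised, and each input channel is divided by its 99th
percentile over the training slides (stored with the model, applied at
prediction).  The features themselves are fed raw — no per-feature
distribution shaping — but their scales span orders of magnitude
(intensities ~400, axis lengths ~10), and without a fixed per-channel scale
a short Adam schedule spends its budget renormalising the first layer.
Prediction tiles the slide with half-patch stride, averages seams and clips
to [0, 1]; smaller slides are reflect-padded with a warning.

## Evaluation

Leave-one-slide-out cross-validation for the table models (n splits);
ordered (validation, test) pairs for the U-net (n·(n−1) splits — 132 at the
study's n = 12).  Metrics are the confusion-matrix ratios (accuracy,
sensitivity, specificity, precision); zero-denominator ratios are reported
as NaN, never 0.  Cell-level truth is the mask value at the centroid.

**Virtual biopsies.**  Square ROIs whose side is √(k · 0.15 mm²) for k
fields of view, sampled uniformly among positions that are ≥ 95% single
class (the purity bound is a parameter; the source material samples "from"
each tissue without stating purity).  Marker and exact-combination
positive-cell percentages are computed per ROI, averaged per class, and
compared with a two-sided Mann-Whitney U test (exact for ≤ 20 tie-free
observations per group, otherwise normal approximation with tie
correction).  The 32 exact-combination rows partition each ROI (sum = 100%).

**Robustness sweeps.**  Threshold sweeps report metrics per threshold;
monotone non-increasing sensitivity and non-decreasing specificity hold as a
theorem of thresholding and are property-tested.  ROI-size sweeps report the
accuracy distribution (and IQR) over repeated seeded draws per size plus a
whole-slide value.  Leave-one-feature-out ablation retrains with one input
dropped and ranks features by the accuracy obtained without them.

## Synthetic data: what it does and does not show

The generator emulates: a smooth random tumour region (Gaussian-filtered
noise thresholded at a coverage quantile); dart-throwing nucleus placement
with a minimum separation; elliptical nuclei with class-conditional
log-normal areas and intensities (fluorescence is positive and
right-skewed); marker-positive sub-populations with configurable per-class
fractions — defaulting to the study's observed per-marker positive-cell
percentages in tumour vs non-tumour tissue (CD3 3.85/8.08, CD4 2.83/6.14,
CD8 0.90/3.21, FoxP3 5.23/3.05, PD-L1 4.00/3.81 percent) — an additive
per-channel autofluorescence baseline, clipped Gaussian pixel noise, and
per-tile integer jitter (anchor tile unjittered so absolute offsets are
identifiable).  The direct table generator bypasses imaging: standard-normal
features with a configurable standardised class shift d on named features.

It does **not** model optics (PSF, spectral cross-talk between
fluorophores), staining artefacts, touching/overlapping nuclei,
within-tissue spatial autocorrelation of features beyond the region mask, or
the inter-patient heterogeneity that dominates real cohorts (where a
feature's correlation with the tumour mask can invert between patients).
Passing tests therefore establish correctness of the measurement and
learning machinery under known ground truth — not clinical performance; the
published patient-level accuracies are not reproducible from synthetic data
and are not claimed.

**Study conditions of the bundled experiments** (all sizes chosen as fixed
package defaults): feature-selection recovery uses d = 2 shifts on five
features at 10 000 cells over 40 seeded runs; the MLP experiment uses d = 3,
20 000 cells, 40 full-sample epochs, three seeds; the U-net experiment uses
four 128-px single-tile slides with strong class separation (tumour nuclei
brighter in DAPI, ~2× larger, CD3-depleted), 2 train / 1 validation / 1 test,
200 epochs, three seeds; geometry recovery uses the generator defaults
(400 cells, 544-px slide, 4×4 tile grid, jitter ≤ 5 px) over 20 seeds.

## Known limitations

* The 68-entry registry is a reconstruction (total and families are
  documented; the itemised original list is not public).
* The AF-correction baseline (5th percentile) is a stated assumption.
* Tiles with detection-free overlaps are unalignable in principle; they keep
  nominal offsets and are excluded as anchors.  At very low cell densities
  this bounds count conservation to the cells actually seen by some tile.
* The NumPy networks are single-threaded CPU implementations sized for
  desk-scale experiments; the full-scale presets (5000 epochs, 256-px
  patches) are provided but not exercised by the bundled experiments.
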