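# Methods

## The screening problem

Fabry nephropathy (FN) shows, on light microscopy, podocytes with pale
vacuolated ("foamy") cytoplasm from glycosphingolipid storage. The
pipeline quantifies that hallmark over annotated, non-globally-sclerotic
glomerular regions of a biopsy and reduces it to one number per patient
— the ZEBRA score — usable as a screening trigger for secondary review.
Two model families run in parallel: a tile classifier (cheap, coarse)
and a pixel segmenter (expensive, quantitative); the score comes from
the segmenter.

## Physical-scale normalisation and tiling

Scanners digitise at different spacings; all learning happens at
0.5 μm/px. An image at source spacing `s` is resampled to size
`round(dim·s/0.5)` with bilinear interpolation (nearest-neighbour for
masks, which must stay binary). Coordinates are 0-based, y-down, tile
windows half-open `[x, x+512) × [y, y+512)`. Tiles are gridded over a
region's bounding box from its top-left with stride 512 (non-
overlapping) and kept when the tile *center* lies inside the region
polygon — a deterministic rule that avoids boundary slivers; a region
smaller than one tile yields a single tile centered on its bounding box
and padded. A tile is labelled *foamy* when its window intersects any
foamy-podocyte polygon with positive area (no minimum-overlap
threshold; the screening intent favours sensitivity).

Annotations travel as QuPath-dialect GeoJSON FeatureCollections, one
file per image, each feature carrying a `classification.name`.
Multi-polygons are split; features without a classification fall back to
`unclassified` with a warning.

## Trainable models

Both models are scikit-learn SGD logistic classifiers trained by
mini-batch `partial_fit` with a constant learning rate, inverse-
frequency class weights computed on the full training labels, and a
seed that fixes initialisation, shuffling and augmentation draws —
epochs/batch-size/learning-rate semantics are therefore explicit and
runs are exactly reproducible on one CPU.

- **Tile classifier**: 35 fixed summary features per tile (8-bin
  per-channel colour histograms, channel means/sds, five gray-level
  percentiles), standardised on the training fold. Defaults: 5 epochs,
  batch 32, η 0.05.
- **Pixel segmenter**: 11 per-pixel features (RGB; RGB smoothed at
  σ = 2 and 8 px; Sobel gradient magnitude; a σ = 24 px gray context
  channel that separates pale lesions *inside* the dark tuft from the
  equally pale background outside it) — the trainable-segmentation
  idiom of ilastik/scikit-image. Training samples 2,000 pixels per
  tile, class-balanced where foreground exists. Probability maps are
  thresholded at 0.5 (masks are nested in the threshold); an optional
  minimum-object-size filter is off by default.

Augmentation, when enabled, is flips, 90° rotations, ±10%
brightness/contrast and ±5% hue jitter — label- and mask-preserving,
deterministic per RNG state.

Cross-validation is 5-fold at **case** level: cases are shuffled by
seed and dealt round-robin, so fold sizes differ by at most one case
and no patient contributes tiles to both train and validation —
the single most important hygiene rule for histology models.

## Aggregation and the ZEBRA score

Tile predictions pool to glomerulus level by *any-positive* (default;
majority and mean-probability rules are selectable), and glomerulus
labels pool to case level by any-positive — one flagged glomerulus
flags the case. The evaluation unit (slide vs case) is whatever id the
tiles carry; the synthetic cohorts use one slide per case.

Per glomerulus, `ZS = 100·fpA/tgA` with `fpA` the predicted foamy area
*intersected with* the predicted glomerular mask (the score is by
definition a proportion of glomerular area) and `tgA` the glomerular
area; regions whose predicted glomerular mask is empty are skipped with
a note. Case score = unweighted mean over glomeruli. The case rule is
`mean ZS ≥ cutoff → FN`, inclusive at the tie so ambiguity resolves
toward sensitivity. The cutoff defaults to the Youden-J maximiser on
the case means; ties in J break toward the lower cutoff, again
favouring sensitivity.

ZS is reported in percent. Published case-level score summaries in this
area are ambiguous between fraction and percent conventions (standard
deviations exceeding means suggest heavy right-skew or a units slip);
this implementation states its unit explicitly and makes no attempt to
match any particular printed convention.

## Statistical protocol

- 2×2-table metrics with undefined ratios (zero denominators) reported
  as missing, never 0.
- AUC-ROC via rank statistics (equals Mann–Whitney pair counting, ties
  ½).
- 95% CIs by percentile bootstrap, 1,000 resamples of individual
  (prediction, label) pairs; resamples with undefined metrics are
  skipped and counted, >50% undefined is an error. A case-level cluster
  bootstrap is not the default because the resampling unit is the
  prediction.
- Youden's J maximised over midpoints between adjacent sorted unique
  scores plus sentinels beyond both extremes.
- Spearman via mid-ranks (ties averaged); zero rank variance reported
  missing.
- Mann–Whitney U with exact two-sided p by enumeration of all
  assignments when the pooled sample is ≤ 12 (valid under ties),
  tie-corrected normal approximation otherwise; significance at 0.05.
- χ² without continuity correction by default (a corrected variant is
  provided), df = 1, zero marginals rejected.

## The synthetic cohort generator

The generator's job is *verifiability*, not realism. Each glomerulus is
a blobby harmonic-perturbed ellipse ("tuft") in a darker eosin or PAS
tint on a pale background, 256 μm canvas, emitted at one of the source
spacings (0.2208 / 0.2506 / 0.25 μm/px) so the rescaling path always
runs. Lesions are clusters of 2–10 overlapping pale discs (radius
3.5–8 μm) with a ~1 μm darker rim, placed greedily inside the tuft
until the mask fraction is within ±0.01 of the target; each disc is
size-clamped so placement can never overshoot, making convergence
deterministic. Ground truth is the *achieved* mask, and
`podocyte ⊆ glomerulus` holds pixel-wise by construction.

Cohort defaults are the study conditions: 10 FN + 10 control cases, 3–5
glomeruli per case, per-glomerulus lesion fractions uniform on
[0.10, 0.30] for lesioned glomeruli, and a 74% lesioned share among an
FN case's glomeruli (the share observed in the real cohort). A positive
case that would sample zero lesioned glomeruli gets one forced, since
an FN case identified by vacuolization necessarily shows at least one
affected glomerulus; the bias on the pooled share is negligible. The
synthetic manual score is `MPVS = 3·(case mean fraction / max
fraction) + N(0, 0.15)` clipped to [0, 3] — a known monotone relation
for correlation tests. Controls carry zero lesions and MPVS 0.

What the generator does **not** emulate: nuclei, tubules, interstitium,
stain variability across centers, sclerosis, or the near-boundary
lesion burdens of real FN (real case-mean scores sit around a fraction
of a percent; the generator's 10–30% fractions are deliberately
separable). Passing tests therefore demonstrate that the machinery is
correct and leak-free — not that the models would reach any particular
performance on real slides.

## Problem sizes and numerical choices

The default end-to-end run uses the 20-case cohort above (~80 tiles),
5-fold CV, 5 classifier epochs and 3 segmenter epochs — chosen so a
full run completes in a couple of minutes on one CPU while every stage
still has both classes in every fold. Score-recovery checks use a
30-case cohort at 0.25 μm/px. Empty-vs-empty Dice/IoU are defined as 1
(a correctly rejected tile is perfect); the default aggregation pools
pixels globally, which sidesteps that convention. Decision thresholds
are 0.5 throughout unless a cutoff is being selected.

## Known limitations

- The trainable models are linear in engineered features; they are the
  pipeline's reference implementation, not competitive histology
  backbones, and the module interfaces (model bundles with patch-size/
  spacing/class metadata mirroring the WSInfer model-card convention)
  are the intended extension point for heavier models.
- Pyramidal WSI decoding is out of scope; the pipeline consumes region
  crops or flat images.
- The ZS's prognostic meaning (eGFR, proteinuria, outcomes) is not
  modelled; the correlation/regression operators exist but the package
  makes no clinical claims.
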