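# Methods

This note describes the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot show.

## Problem setting

Whole-slide images (WSIs) of H&E-stained tumor sections are gigapixel
pyramids; labels (histological subtype, molecular subtype, mutation status)
exist per patient, not per pixel. The pipeline turns each slide into many
small samples — 299×299-pixel tiles — trains a convolutional classifier on
tiles with inherited (weak) patient labels, and aggregates tile predictions
back to patients. The distinguishing idea is *multi-resolution tile sets*:
three co-registered tiles of the same anatomical region at 10×, 5× and 2.5×
equivalent magnification, consumed as one sample by a three-branch network
(Panoptes), so the classifier sees cellular detail and architectural
context simultaneously.

## Slide model and tiling geometry

A slide is an image pyramid with strictly increasing downsample factors;
all coordinates are 0-based half-open pixel rectangles at level 0. A
requested magnification equivalent maps to a level-0 footprint of
`size_px × base_magnification / target` pixels on a side; the nearest
pyramid level at least as fine is cropped and resampled (area averaging for
integer factors, bilinear otherwise). Nominal power comes from explicit
metadata when present, else from mpp (0.25 µm/px ≙ 40×, 0.5 ≙ 20×, nearest
of the two), else from a user-supplied value; a file with none is rejected.

The slide is partitioned into non-overlapping 299-pixel cells at 2.5×
(partial edge cells dropped, never padded). Each cell contains a 4×4
lattice of 10× tiles and a 2×2 lattice of 5× tiles, so each higher-
resolution tile covers exactly one fourth of the next lower one and a full
cell yields 16 tile sets (area ratios 1:4:16, asserted by rectangle
arithmetic in tests).

**Filter.** A pixel is background/contaminant iff all three RGB channels
are < 50 (dark debris) or all three are > 200 (white background); a tile is
discarded iff *more than* 40% of its pixels qualify (exactly 40% is
retained — the boundary is strict). A tile set is kept only if all three
member tiles pass; the filter runs on raw pixels before any color
normalization, since normalization remaps background. Filtering per member
tile (rather than per set or per 10× tile alone) guarantees every network
branch sees informative pixels.

## Stain normalization

Beer–Lambert optical density `OD = −log((I+1)/256)` is linear in stain
concentrations: `OD ≈ Cᵀ S` with `S` a 2×3 unit-row nonnegative basis
(hematoxylin, eosin) and `C ≥ 0`. The tile's basis is estimated by sparse
NMF — an L1 penalty (weight 0.10) on concentrations, OD background
threshold 0.15, 99th-percentile concentration scaling — solved by
alternating a closed-form nonnegative coordinate-descent lasso step for `C`
with a ridge-tethered projected least-squares step for `S`
(`μ‖S − S_prior‖²`, μ = 30, prior = the Ruifrok H&E basis, which also
warm-starts the solve, making it deterministic without random
initialization). The tether is negligible when a tile contains near-pure
pixels of both dyes and keeps the basis anchored to a plausible H&E
geometry when the factorization is ill-posed (one dye never unmixed —
common in stroma-dominated tiles). Normalization rescales source
concentrations by reference/source 99th-percentile ratios and recombines
with the reference basis (default: Ruifrok vectors with conventional
maxima 1.9705/1.0308); absolute output colors are therefore
convention-dependent, and only invariance properties (idempotence on
reference-rendered tiles, global stain-scale invariance, background
preservation) are asserted.

Estimation is per tile by default — a per-slide mode (one basis and one
scaling from the coarsest pyramid level) is offered for speed. Per-tile
mode is also what the desk-scale study uses: the normalization of a tile
then depends only on that tile's own content, so identically distributed
tiles remain identically distributed after normalization.

## Cohort handling

Labels are weak per-patient binary outcomes; all partitioning is at the
patient level. Mixed mode splits patients 8:1:1 (train:validation:test),
stratified by class via largest-remainder apportionment per class with a
global correction so overall sizes are exact, every partition guaranteed at
least one patient of each class (infeasible stratifications raise).
Cohort-independent mode holds out one source cohort entirely as the test
set and splits the remainder 9:1. Class weights equalize the training
composition: `w_c = N_train / (2 N_train,c)` over training tile sets.
Tile sets serialize into sharded length-prefixed binary records (JSON
header + raw tile bytes) under a manifest with per-shard sha256 checksums;
reads verify checksums and reproduce any seeded shuffle order. Missing
age/BMI are median-imputed from the training partition with missingness
flags appended.

## Architectures

Panoptes1–4 consume a tile set through three parallel branch extractors
that stay separate until their final feature maps are concatenated on the
channel axis, followed by (Panoptes3/4 only) a 1×1 feature-pooling
convolution, global average pooling, an optional 16-unit clinical embedding
(standardized age + BMI + missingness flags through a 4→16→16 MLP,
concatenated after pooling), dropout with keep probability 0.3, and the
final fully connected layer. Each branch carries an auxiliary GAP+FC
classifier head; auxiliary losses are averaged over branches and weighted
0.4 (the Inception lineage's conventional auxiliary weight — the loss
weight is not pinned down anywhere else, so the lineage default is used).
Panoptes1/3 branches follow the inception-resnet-v1 channel plan,
Panoptes2/4 the wider v2 plan. The five baselines (inception v1/v2/v3,
inception-resnet v1/v2) are the corresponding single-branch networks fed
only the 10× member tile.

Because no deep-learning framework is assumed, the networks run on a
self-contained numpy engine (`panoptes.nn`): im2col convolution, batch
normalization, ReLU, inverted dropout (keep-probability convention),
channel concatenation, scaled residual shortcuts, global average pooling,
dense layers, Adam, and explicit backward passes verified against numeric
differentiation. Branch extractors follow the inception / inception-resnet
block structure (parallel 1×1/3×3 paths, 1×1 projection, scaled residual
add, stride-2 reductions) at reduced depth so the family trains on one
CPU; the per-family channel plans keep the nine names genuinely distinct.
`width_multiplier` scales every channel count uniformly (floor 4), and
`input_px` may be reduced to 75 for desk runs; parameter counts are
monotone in width. Checkpoints store the weight arrays together with the
architecture-config fingerprint and refuse to load into a mismatched
config.

## Training schedule

Weighted softmax cross-entropy on the main logits plus 0.4 × the mean of
the branch auxiliary cross-entropies, optimized with Adam (β₁ 0.9, β₂
0.999, ε 1e-8 — the framework-default moments, recorded here because no
other values are specified). Full-scale defaults: batch 24 (Panoptes) / 64
(baselines), learning rate 1e-4, a 100-batch validation pass every 1000
iterations and additionally whenever training loss reaches a new global
minimum after iteration 30000; checkpoint on each new validation-loss
minimum; stop when no minimum has occurred for 10000 iterations, enforced
only after iteration 100000. The state machine is identical at any scale —
desk runs shrink every counter (validate every 100 with 8 batches,
patience 400, stop floor = cap = 600 iterations) and raise the learning
rate to 1e-3, which at these widths and sample sizes reaches the same
qualitative optimum in minutes. Dropout keep 0.3 is implemented literally
as keep-probability 0.3 (dropping 70% of activations — aggressive, but
that is the stated rate). Batches are contiguous slices of per-epoch
permutations drawn from the schedule seed, so runs are bit-reproducible
regardless of data-loading parallelism.

## Evaluation

One prediction row per tile set. Per-patient scores are the arithmetic
mean of the patient's tile-set scores; patient-level metrics treat each
patient as one sample (the alternative reading — averaging per-tile
*metrics* — is not used). Classification uses a strict > 0.5 cutoff.
AUROC is the Mann–Whitney probability with ties counted ½ (exhaustively
checked against the pairwise oracle); AUPR is average precision. 95% CIs
are percentile bootstrap (n = 1000) over patients or tile sets; single-
class resamples are redrawn, and metrics undefined for single-class tables
are reported as missing, never as 0. The tile-level group comparison is a
one-sided unpaired rank-sum test (exact enumeration for tie-free samples
up to 20 per group, normal approximation with tie correction otherwise;
the groups have unequal sizes, so an unpaired form is the only mechanical
possibility). Architecture comparison: 50 subsamples at an 80% rate
without replacement per model, AUROC per subsample, one-sided Welch t-test
of A > B.

## Multi-model POLE composition

POLE score = aggregation over member models (CNV-H, CNV-L, MSI-high) of
(1 − member positive score); arithmetic mean by default (the minimal
reading of "aggregating"), product as an option. Exact identities
(all-0 → 1, all-1 → 0) and monotone decrease in every member score hold by
construction and are asserted. Tile-level composition pairs members by
tile-set id when they share a tiling; otherwise composition happens at
patient level.

## Visualization

tSNE (perplexity 30, 1000 iterations, PCA initialization, deterministic
per seed) of penultimate feature vectors for a random sample of up to
20000 tiles, preceded by projection onto at most 100 principal components;
points colored by prediction score on a fixed 0–1 scale, with an optional
tile-thumbnail mode placing at most one thumbnail per collision-grid cell.
Heatmaps write each tile set's score into the 299-pixel 10×-grid cell of
its anchor (grid dims = floor(10× extent / 299)); unfiltered cells are
missing and render transparent; overlays blend a diverging colormap with
midpoint 0.5 over a slide thumbnail.

## Synthetic data

The generator renders H&E-like slides from the same two-dye OD model the
stain module assumes: eosin stroma (OD 0.42 ± 0.05 low-frequency noise),
Gaussian "gland" blobs (σ ≈ 60 px, spacing 500 px on a lightly jittered
lattice) of two types — hematoxylin-rich (purple) or eosin-rich (pink) —
and small hematoxylin nuclear dots inside glands. Slides render at 10×-
equivalent base resolution (nominal 1 µm/px) with area-averaged 2× and 4×
pyramid levels; white margins and dark contaminant patches are planted on
request, and a ground-truth mask ships with every slide.

Class signal is planted at a chosen scale:

- **macro**: blob *types* are spatially segregated into ~800 px domains in
  class 1 and independently random in class 0. Two safeguards make this
  signal invisible below the 2.5× field. First, the per-slide H-blob
  *count* is drawn from the same Binomial(n, ½) in both classes, and the
  classes differ only in *which* blobs are hematoxylin-rich: blobs are
  ranked by `effect × domain-field + (1 − effect) × noise` and the top
  n_H become H, so at effect 0 the assignment is independently random and
  the per-slide type composition distribution is exactly class-identical
  at any effect (otherwise a patient's mean tile score, which is linear in
  the slide's type ratio, would leak class through the segregation-induced
  ratio variance). Second, a single 10× tile (299 px, smaller than the
  minimum gland separation) sees at most one gland, whose type is a fair
  coin in either class — 10× tile marginals are identical by construction
  (verified: per-tile mean/std distributions are class-indistinguishable).
  Only a window covering several glands (the 2.5× field) can see the
  co-occurrence pattern.
- **micro**: nuclear-dot density inside glands scales by (1 + effect) in
  class 1 with identical macro arrangement — visible at 10×.
- **none / effect 0**: classes are identically distributed (same seed ⇒
  byte-identical renders).

Blob spacing, σ and jitter were chosen so adjacent glands stay ≥ 350 px
apart: a 10× window then cannot contain two gland centers and the macro
signal is genuinely invisible to a single-resolution 10× model. What the
generator does **not** emulate: nuclei-scale morphology, texture families
beyond Gaussian blobs and dots, scanner noise and compression artifacts,
stain variability across a slide, tissue folds, pen marks. Passing the
desk-scale study therefore shows the *pipeline* can recover
scale-localized signal through the multi-resolution pathway; it says
nothing about performance on real histology.

## The desk-scale signal-recovery study

Conditions: 40 patients (1 slide each, 2392×2392 px at 10× base → 4 grid
cells → up to 64 tile sets per slide), class balance ½, macro signal at
effect 1.0; per-tile stain normalization; tiles resized to 75 px;
Panoptes1 and the inception-resnet-v1 baseline at width multiplier 0.1;
mixed 8:1:1 split; desk schedule (600 iterations, learning rate 1e-3,
batch 24/24 vs 64). Expectation: Panoptes' per-patient test AUROC is high
(the 2.5× branch sees the domains), the 10×-only baseline's bootstrap CI
covers 0.5, and on an effect-0 cohort Panoptes' CI covers 0.5 as well.
BLAS threading is pinned to one thread during the study so the run is
reproducible across machines. With a 4-patient test set the AUROC is
coarse (steps of ¼); the per-patient CI is wide by construction, which is
exactly why the chance arms are assessed by CI coverage rather than point
values.

## Numerical and degenerate-input conventions

- Resampling: box average for integer factors, bilinear otherwise;
  repeated reads are pure.
- Tiles with fewer than 100 tissue pixels (max-channel OD > 0.15) are
  unstainable: kept unnormalized and flagged, never silently dropped.
- Single-class metric tables report missing metrics; bootstrap redraws
  single-class resamples (bounded); zero-width CIs are legitimate for
  degenerate tables.
- Splits with a class too small to place one patient per partition raise
  rather than silently unbalancing.
- All randomness flows from explicit integer seeds (generator specs,
  splits, shuffles, dropout, tSNE); no global RNG state is consumed.

## Known limitations

- Branch extractors are reduced-depth relatives of the named inception
  topologies, not layer-for-layer reproductions; contracts (three
  branches, auxiliary heads, concatenation point, pooling, clinical merge)
  are faithful.
- The record store is a package-specific framing, interoperable in spirit
  (streamable, shardable, checksummed) but not a TFRecord file.
- Vendor WSI formats (SVS/SCN) are not read directly; pyramidal TIFF is
  the supported container.
- Per-slide stain normalization trades the per-tile mode's locality for
  speed; on slides whose stain ratio varies regionally the two modes
  differ visibly.
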