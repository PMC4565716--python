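# Methods

`petromics` implements and compares two strategies for predicting
neoadjuvant-chemotherapy response from a single pre-therapy ¹⁸F-FDG PET
scan of an oesophageal tumor: a hand-crafted 103-feature radiomic
descriptor feeding tuned classical classifiers, and slice-fusion
convolutional networks trained directly on the tumor slices. Because the
clinical cohort that motivates the package (107 patients; 38 responders,
69 non-responders) is not publicly deposited, the package ships a phantom
generator that emulates its geometry and class structure, and every
pipeline stage is validated on phantoms.

## Phantom model

A phantom tumor is a superellipsoid lesion support (exponent 2.5, boxier
than an ellipse) with per-slice radius modulation, a smooth intensity
envelope falling from the core to the boundary, and a multiplicative
log-normal texture:

    uptake(v) = base_uptake · envelope(v) · exp(h · G(v))

`G` is zero-mean, unit-variance spatially correlated Gaussian noise
(Gaussian-smoothed white noise; smoothing width = correlation length /
voxel spacing per axis). The heterogeneity amplitude `h` is the class
knob: responders default to h ≈ 0.2, non-responders to h ≈ 1.5, encoding
the working hypothesis that heterogeneous uptake marks chemo-resistant
tumors. An optional separate axial correlation length decouples
inter-slice coherence from in-plane texture, and a slice-shuffle mode
permutes a volume's axial order after generation (with a
displacement-enforcing permutation, so a shuffled volume never resembles
the ordered one). The inter-slice benchmark pairs a coherent class
(axial correlation 40 mm: adjacent slices nearly repeat) with an
axially *independent* class: classes differ only in the latent field's
axial structure. One caveat is stated openly: the per-tumor SUVmax
normalization converts axial incoherence into a weak per-slice
brightness cue (an incoherent tumor's slices are systematically dimmer
relative to its global maximum), so the single-slice model is above
chance on this benchmark; the three-slice model, which sees the
coherence directly, dominates it.

Geometry follows the cohort: 4–32 axial slices per tumor, in-plane
extents between 13×16 and 93×79 pixels at 4.7×4.7 mm with 3.27 mm slice
thickness. Cohort slice counts are drawn from a log-normal clipped to
[4, 32] with median 10; this reproduces the cohort's reported triplet
yield (~9 triplets per tumor, ~886 triplets from a 96-tumor training
set). Background voxels sit at 10% of each slice's lesion maximum so the
40% delineation rule recovers the lesion cleanly; the fraction is
configurable to build ragged-segmentation stress tests. Default cohort
composition is the study imbalance, 38 responders / 69 non-responders.

The phantom deliberately omits scanner physics: no point-spread function,
scatter, attenuation or reconstruction artefacts, and no anatomical
realism beyond per-slice extent variation. Tests passing on phantoms
therefore certify the *pipeline* (delineation, descriptors, training,
voting, evaluation) under a known generative model — not performance on
real PET data.

## Delineation

The tumor ROI is delineated per axial slice by a relative threshold:
voxels with uptake below 40% of that slice's maximum are excluded; voxels
exactly at the threshold are retained. The rule is applied verbatim — no
connected-component cleanup by default (a largest-component option exists
behind a flag). Because the rule is relative it is exactly invariant to
rescaling the volume, and raising the fraction can only shrink masks.
The input volume is assumed to be a lesion-containing crop; the package
does not model the physician's initial localisation.

## The 103-feature descriptor

In-mask SUVs are quantized into Ng = 64 equal-width levels between the
ROI minimum and maximum (level = 1 + ⌊(v−min)/(max−min)·Ng⌋, clipped),
making all matrix features invariant to positive affine rescaling of
uptake. 64 levels is the common PET radiomics default; the count is
configurable.

Families (85 texture + 18 SUV = 103, pinned in `catalog.yaml`, the single
versioned source of truth for feature identity and order):

* **First-order (26)** — central tendency, spread, percentiles, shape
  (skewness/kurtosis), energy, histogram entropy/uniformity/mode (64
  bins). Population (1/N) variance convention throughout.
* **GLCM (20)** — Haralick-family features of the symmetrized gray-level
  co-occurrence matrix at distance 1 over the 13 unique 3-D directions,
  each feature averaged over directions with at least one valid pair.
* **GLRLM (13)** — the classical run-length set (emphases, gray-level and
  run-length non-uniformity/variance, run percentage), direction-averaged;
  a mask gap terminates a run; runs partition the in-mask voxels exactly.
* **GLSZM (13)** — size-zone analogues over 26-connected iso-level zones
  (direction-free); zones partition the in-mask voxels exactly.
* **GLDM (4)** — mean, entropy, variance and contrast of the absolute
  level-difference histogram pooled over the 13 directions.
* **NGTDM (5)** — coarseness, contrast, busyness, complexity, strength
  from per-level deviations against the 3×3×3 in-mask neighbor mean.
  Coarseness is 1/(ε + Σ pᵢsᵢ) with ε = 1e−12, capping the flat-ROI case.
* **Fractal (4)** — per-voxel fractal dimension by differential box
  counting in a moving 5×5 window (box sizes 2..w−1, complete blocks
  only, counts normalized so a flat window reads exactly dimension 2);
  map mean and SD; Hurst exponent by rescaled-range analysis of the
  in-mask intensity sequence (0.5 on degenerate input); mask-aware
  gliding-box lacunarity var/mean² + 1 (exactly 1 for constant uptake).
* **SUV (18)** — SUVmax/min/mean/median/std/peak (1 cm³ spherical
  neighborhood of the hottest voxel), percentiles, range, IQR, total,
  max/mean ratio, metabolic tumor volume (cm³) and total lesion
  glycolysis (SUVmean × MTV). Some summaries duplicate first-order
  statistics under their clinical names; the catalog mirrors clinical
  reporting rather than de-duplicating.

Degenerate ROIs are handled by defined fallbacks (correlation, skewness,
kurtosis, CV → 0 on zero variance; empty directions excluded from
direction averages), so descriptors are always finite; a non-finite value
is a hard error naming the feature.

Two numerical notes discovered while validating the phantom benchmarks.
First, GLCM *entropy* is not a monotone readout of the phantom's
heterogeneity amplitude: the multiplicative exp texture is heavy-tailed,
so equal-width binning concentrates voxels into few levels at high `h`
and entropy falls; contrast-type features (GLCM/GLDM contrast, GLDM
mean, NGTDM coarseness) are the monotone discriminators and carry the
class-separation tests. Second, differential box counting normalizes box
heights by each window's own intensity range, which cancels most of a
multiplicative amplitude change; mean FD therefore separates the phantom
classes only directionally (majority of paired seeds), not uniformly.

## Classical models

Logistic regression, gradient boosting, random forests and SVM
(polynomial kernel by default — degree and C on the grid; linear/RBF
available) are tuned by grid search maximizing mean accuracy over
10-fold cross-validation, then refit on the full training set. Features
are z-scored with training statistics before LR/SVM/PCA; the optional
PCA path projects onto the 10 largest principal components of the
standardized (correlation-scale) features, fit on training data only.
CV folds are stratified and seed-deterministic by default; stratification
is switchable to a plain random partition. Grids are pinned in
`DEFAULT_GRIDS` (e.g. GB: 100/300 trees, depth 2/3, learning rate
0.05/0.1).

GB variable importance uses the summed squared split-improvement measure
averaged over the ensemble's trees, rescaled so the top feature scores
exactly 100; it is only defined in feature space, so PCA models are
rejected.

Two SUVmax-only baselines: a ROC-derived threshold maximizing TPR + TNR
over the observed training values (ties resolve to the smallest
qualifying threshold), and the training-median threshold. Both call a
tumor a responder when its SUVmax falls *below* the threshold.

## Slice-fusion CNNs

Every ROI slice (uncropped frame, out-of-mask pixels zeroed, intensities
divided by the tumor's SUVmax) is embedded centred in a 100×100 zero
background. The 3S variant fuses each triplet of adjacent slices into a
3-channel sample (an m-slice tumor yields m−2 triplets); the 1S variant
uses single slices as 1-channel samples. Training sets are augmented
with in-plane rotations by κ·60°, κ = 1..5 (bilinear, zero fill), and
balanced across classes by oversampling.

The network is four convolution (5×5, 'valid') + 2×2 non-overlapping
max-pool stages with tanh activations, a fully connected tanh layer, and
a 2-way softmax; the spatial trace from 100×100 is 48 → 22 → 9 → 2. The
default feature-map widths (4, 8, 8, 8) with a 32-unit FC layer are sized
for CPU training on phantom cohorts; `CNNConfig.wide()` gives the
higher-capacity (16, 32, 64, 128)/256 layout, and ReLU and FC-dropout
exist as flags (off by default — they did not change phantom results).

Training minimizes the summed negative log-likelihood by mini-batch SGD
(batch 32, learning rate 0.02, momentum 0.9, per-sample gradient-norm
clipping at 1.0) with analytically derived gradients, verified against
finite differences in the test suite. The learning rate and clipping were
fixed on controlled toy tasks: with momentum 0.9 an effective rate of
0.5 diverges, and unclipped training shows a reproducible
find-then-collapse instability on relational (cross-channel) signals.
30% of the training *tumors* — not samples — are held out for epoch
selection and the best-validation-epoch weights are returned; holding out
at the sample level lets augmented rotations of one triplet straddle the
boundary, and epoch selection then rewards memorization. Implementation
notes: convolutions run as shift-and-accumulate skinny matmuls in a
channels-last layout, and the activation is applied after pooling
(exactly equivalent for monotone activations, much cheaper on the early
feature maps). Everything is float32 and seed-deterministic in
single-threaded execution.

Decision rule: a sample votes responder when its predicted responder
probability exceeds 0.5; a probability of exactly 0.5 is a tie — scored
as *wrong* during evaluation and voting 0 at prediction time (the tie
convention needs a deterministic completion when no label is available).
The tumor is called a responder when the vote fraction strictly exceeds
0.5; the tumor-level tie resolves to non-responder.

## Comparison protocol

The experiment plan mirrors the study: 96 training / 11 test tumors,
repeated over three *disjoint* test sets drawn from one seeded
permutation, every roster model trained per repeat, and mean ± population
SD over repeats reported. Splits are unstratified by default (a stratify
flag exists); a model failure in one repeat is recorded as missing and
the run continues; metrics recomputed from the stored per-subject
predictions equal the reported aggregates exactly.

Metric convention: the reported "sensitivity" is the fraction of
non-responders correctly identified and "specificity" the fraction of
responders correctly identified — the swapped usage of the study this
protocol mirrors, implemented verbatim and flipped by
`convention="standard"`. Single-class truth leaves a rate as missing,
never 0.

## Benchmark scales and expected behaviour

The stock benchmarks (also what `scripts/acceptance.py` runs) are sized
for a single CPU:

* *Separated heterogeneity* (0.2 vs 1.5), 107 phantoms, 96/11 × 3 with
  the small CNN at 3 epochs: 3S-CNN recovers the class structure
  essentially perfectly (>90% mean test accuracy; typically 100%).
* *Inter-slice contrast* (coherent vs slice-shuffled, per-slice
  statistics identical), 28 tumors per seed, 16 train / 12 test, 8
  epochs: 3S beats 1S on a large majority of seeds, with 1S near chance
  at tumor level.

These phantom tasks are planted-signal recoveries; they demonstrate that
the pipeline can extract the signals it claims to extract, not that any
particular accuracy transfers to clinical data.

## Known limitations

* Phantom realism is bounded by the few geometric facts the cohort
  reports; intra-tumor SUV distributions are a modelling choice.
* The exact bin count, direction sets, and the identities of the 26
  first-order and 18 SUV summaries are pinned choices (the source catalog
  is not published); the manifest makes them explicit and versioned.
* The fractal family is computed per slice (2-D windows); Hurst and
  lacunarity summarize simple 1-D/3-D statistics and are not calibrated
  estimators.
* Validation accuracy is an epoch-selection signal over a handful of
  held-out tumors, not a performance estimate; the protocol's test tumors
  are the only honest readout.
* On the strictest inter-slice control (slice-shuffled volumes, identical
  per-slice realizations), both CNN variants remain at chance for the
  cohort sizes tractable here: the pure order signal is too weak for this
  capacity/data regime. The inter-slice benchmark therefore contrasts
  coherent with independently textured fields, where the single-slice
  model retains only weak indirect cues.
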