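# Methods

This note documents the models, parameter choices and numerical decisions
behind `spinefuse`, and what the synthetic benchmarks do and do not show.

## Synthetic phantom cohort

The generator emulates a single-center cohort of preoperative spinal MRI
(three intramedullary tumor classes, co-registered T1/T2/contrast-enhanced
sequences, 93/118/105 cases) whose images are not public. It reproduces
the cohort's *published summary statistics*, not its images.

**Component sizes.** Each class carries (mean, sd) volume statistics on a
cm³ scale for three components — tumor, edema, cavity. Draws come from a
log-normal with `σ² = ln(1 + sd²/mean²)`, `μ = ln(mean) − σ²/2`, which
matches both moments exactly and guarantees positivity; this matters
because several cells have sd > mean (e.g. hemangioblastoma tumor
2.3 ± 4.9 cm³), which no truncated-normal parameterization can honour.
A drawn volume V renders as the great-circle area of the equivalent
sphere, `A = π(3V/4π)^{2/3}` cm², converted to pixels via the pixel
spacing (default 0.5 mm isotropic), because the pipeline operates on
single axial slices. The column headers of the published size table are
garbled (one unit annotation for three columns); all three components are
treated as cm³ volumes.

**Geometry.** A bright canal stripe (Gaussian cross-profile, σ = 6 px)
sits at a column drawn uniformly in the central 50% of columns. The tumor
is an ellipse centered in the canal, vertically offset from the image
center by a definite amount (uniform in [size/32, size/8] px, random
sign): the analysed slice is taken through the lesion, but a lesion dead
on the horizontal image midline is the degenerate case of quadrant
localization, so the phantom represents the generic, off-center
configuration. Edema is an annulus around the tumor. The cavity is
syrinx-like — a thin fluid column along the canal (semi-axis capped at
8 px across, length from the drawn area), offset up or down the cord —
rather than a free-floating blob, matching intramedullary morphology
qualitatively. Intensities: per-component offsets in [−1, 1] added inside
each region, scaled by a per-modality contrast gain (T1 0.7, T2 1.25,
CE 1.0, each with 5% seeded scanner jitter); plus a smooth Gaussian
texture field (correlation length `texture_scale`) and white Gaussian
noise (default σ = 0.02). With zero offsets and noise off, every channel
equals the deterministic canal template exactly — a useful null.

**Two profile sets.** `DEFAULT_PROFILES` carries the published per-class
statistics; under them the three classes overlap heavily (as real ones
do), and a fused-feature forest reaches only ~0.6 held-out accuracy at
n = 90 — the phantom deliberately does not manufacture separability the
published statistics do not imply. `strong_separation_profiles()` is a
recovery benchmark with exaggerated geometric/contrast differences
(bulky-tumor / edema-dominant / syrinx-dominant); a correct pipeline
classifies it almost perfectly, so end-to-end tests assert ≥ 0.90 there.
Passing on phantoms shows the plumbing recovers planted signal and stays
calibrated under null labels; it does not certify performance on clinical
images, whose texture, artifacts and co-registration errors the phantom
does not model.

**Augmentation.** Flips (p = 0.5 each), rotations up to ±10°,
multiplicative intensity scaling in [0.9, 1.1] (chosen to parallel the
±10° rotation bound), additive Gaussian noise with σ ∈ [0.01, 0.05].
Geometric transforms apply identically to all channels; intensities are
re-clipped to [0, 1].

**Seeds.** Case i of a cohort uses `base_seed·10⁶ + i`, collision-free at
cohort scale; every output is a pure function of seed and parameters.

## ROI localization

The midline is the argmin over candidate columns (central 50% of the
width, both sides non-empty) of the absolute difference between whole-
column means left and right of the split; ties break toward the column
nearest width/2, then the smaller index. Whole-column means are the
simplest reading of "left–right similarity by mean intensity" that admits
a brute-force oracle, and the objective is invariant to adding a constant
to the image.

The quadrant step selects, among the four quadrants cut at (h/2, m*), the
one with the highest mean intensity inside a vertical band of width
0.2·width centered on the midline, then recursively bisects the selected
region perpendicular to its longer side (depth 2), keeping the half with
the higher band mean, and finally expands symmetrically to at least
64 px per side, clipped to the image. Subdividing the *selected* region
(rather than the "non-relevant" ones) is a deliberate choice: it is the
only reading consistent with converging on the bright canal region in
non-centered scans. Coordinates are 0-based, half-open, row-down.

On 100 default-profile phantoms the detected ROI contains the true tumor
centroid in 98–100 of 100 cases; residual misses are lesions straddling
the quadrant boundary.

## Preprocessing

Histogram equalization quantizes the image to 256 bins over its own range
and maps each pixel through the normalized empirical CDF — monotone,
parameter-free, constant-safe, and idempotent up to one bin width.
Standardization is crop → equalize → bilinear resize to 224 × 224 →
min–max rescale to [0, 1] (constant crops map to zeros). Equalizing
*inside* the ROI maximizes local lesion contrast, which is the stated
purpose of the step; the order is fixed so tests are stable. The ROI is
detected on the first listed channel and applied to all (channels are
co-registered).

## Feature extraction and fusion

**Handcrafted block.** SIFT keypoints and 128-d descriptors are computed
on the 8-bit quantization of the standardized slice (scikit-image
implementation); descriptor rows are L2-normalized. Constant or
feature-free images yield an empty set. A variable-size descriptor set
becomes exactly 512 values by pooling four per-dimension moments — mean,
sd (ddof 0), max, min — chosen over codebook clustering because pooling
is deterministic, dimension-exact and permutation-invariant; an empty set
pools to the zero vector. Keypoints are implicitly restricted to the
lesion region by extracting them from the ROI crop, keeping the pipeline
fully automatic.

**Deep block.** The contract is image (3 × 224 × 224, channels replicated
from one modality) → 4096-d vector. The default backbone is a stub:
channel-wise 8× average pooling, then a fixed random linear projection
`W ∈ R^{4096×2352}` with i.i.d. N(0, 1/in_dim) entries from a seeded
generator, rows centered to zero mean, followed by half-wave
rectification. Row-centering makes each unit ignore the image's DC level;
without it the shared background of equalized slices pins roughly a
quarter of the units at exactly zero across a whole cohort. The stub is
deterministic, download-free, Lipschitz (bounded by the max absolute row
sum of the effective map) and exactly reproducible by a three-line
oracle. A pretrained VGG16 (penultimate fully-connected activation,
classification layer removed, standard ImageNet input normalization) is
available behind the same contract when torchvision is installed; it is
a plug-in, not a test dependency.

**Fusion** is plain concatenation, handcrafted first: spans
sift = [0, 512), deep = [512, 4608), re-checked at runtime. One fused
vector per case from a single configured modality (default T2): the
4608-d arithmetic admits exactly one modality per vector, and multi-
modality combination is deliberately out of scope.

## Wrapper feature selection

A candidate is a binary mask over columns; its fitness is stratified
k-fold (default 5) cross-validated accuracy of the configured forest on
the selected columns, with fold assignment and forest seed fixed per
evaluator so identical masks always score identically. The empty mask
scores 0 without training. Evaluations are cached by mask bits — caching
is purely an optimization.

The search itself (population 30, 50 iterations by default) uses two
moves per individual per iteration, echoing the lyrebird's
escape/mimicry behaviour: ESCAPE copies each bit with probability 1/2
from a randomly chosen fitter member and then flips bits at `flip_rate`
(default 2/D); HIDE flips a Binomial(D, flip_rate) subset (at least one
bit) of the individual's own mask. The escape probability decays linearly
from 0.5 to 0.1; moves are accepted only if fitness does not decrease;
elite masks are replaced only by strictly better candidates, so the
best-so-far trace is monotone. These dynamics are this package's design:
only the encoding (binary masks) and the fitness (5-fold CV RF accuracy)
are externally fixed. Fitness ties break toward fewer selected columns,
then lexicographically — parsimony as the tie-break.

`exhaustive_select` enumerates all non-empty masks (refusing D > 12) with
the *same* evaluator and is the oracle in tests: the search matches its
optimum on the D = 8 benchmark in ≥ 4/5 seeds and can never exceed it.

## Classification and evaluation

Forest: 100 trees, max depth 20, Gini, balanced class weights, seeded,
single-threaded for reproducibility.

Split: stratified 70/15/15. Overall sizes are `round(0.70·n)`,
`round(0.15·n)`, remainder, allocated across classes by largest
remainder; per-class proportions stay within one case of target (e.g.
93/118/105 → 221/47/48). Selection and final fitting use train+val; the
test split is untouched until evaluation.

Metrics for the 3-class problem are macro one-vs-rest throughout:
sensitivity = macro recall, specificity = macro TN/(TN+FP), F1 = macro
F1, AUC = macro OvR from predicted probabilities. Classes absent from
the truth vector are excluded from macro averages with a warning.
Confidence intervals are 95% percentile bootstrap over B = 1000
case-level resamples (cases are the independent units; prediction-level
resampling would understate variance); single-class resamples are
redrawn.

Cross-validation is stratified k-fold with an optional per-fold selector
callback that sees training folds only — no selection leakage; k = n
falls back to plain leave-one-out, where stratification is undefined.

The ablation evaluates five variants under one shared split: each block
alone → RF, fused → RF, deep → selected RF, fused → selected RF. On
features where the two blocks carry independent planted signal, fusion
loses at most 0.02 accuracy to the best single block and selection loses
at most 0.02 to plain RF, across seeds.

## Problem sizes used in the test suite

Oracle and calibration checks run at reduced, stated sizes chosen to keep
the suite routine on a laptop: selector-vs-oracle on D = 8 with a
10-tree/depth-6 forest and 3 folds (the comparison is evaluator-internal,
so forest size cancels); metric-panel equivalence exhaustively for label
vectors up to length 4 over 3 classes plus 300 random vectors per length
5–8; bootstrap coverage at n = 200 with B = 200 over 100 repeats;
end-to-end recovery and null calibration on a 90-case strong-separation
cohort; run-level determinism on a 21-case cohort with reduced search
budgets.

## Known limitations

- The phantom is a 2-D intensity cartoon: no k-space/MR physics, no bias
  fields, no partial-volume effects, no inter-case anatomy variation
  beyond component geometry; conclusions transfer to clinical data only
  at the level of pipeline correctness.
- The stub backbone is a random-feature embedding, not a semantic one;
  its class separation on phantoms is well below the handcrafted block's
  and it exists to exercise the 4096-d contract deterministically.
- Quadrant localization degrades for lesions centered exactly on the
  image midline and for slices where a dark fluid structure dominates the
  brightest-band heuristic.
- A single modality feeds each fused vector; fusing modalities at the
  feature level is out of scope.
- The recorded deep-training hyperparameter block in run configs is
  provenance only — the pipeline contains no trainable network.
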