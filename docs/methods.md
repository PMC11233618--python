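# Methods

This note documents the models, estimators, numerical choices and study
conditions implemented in `affectencode`, and what the synthetic-data
validation does and does not establish about real data.

## Feature spaces and design matrices

Images are labeled with one of 21 mutually exclusive semantic categories
(12 animate: six human categories, two mammal categories, bird, fish,
reptile, insect; 9 inanimate: foods, objects, buildings, sceneries), a
valence code in {-1, 0, +1}, an arousal code in {0, 1}, and any of 18
binary semantic-emotion (SE) flags. Two rarely-used categories (Plants,
Vehicles) exist behind a flag and are excluded from default spaces.

Label-driven spaces:

| space          | features | construction                                     |
|----------------|---------:|--------------------------------------------------|
| CSVA           | 144      | 21 x 3 x 2 compound one-hots + 18 SE bits         |
| SemanticOnly   | 21       | category one-hots                                 |
| ValenceArousal | 6        | 3 x 2 compound one-hots                           |
| SVAA           | 81       | animate categories crossed, inanimate plain       |
| SVAI           | 66       | inanimate categories crossed, animate plain       |

Every encoded vector has exactly one bit set in its mutually exclusive
block; SE bits are independent. Feature ordering is part of the on-disk
contract (manifest JSON).

Valence is resolved across repeated categorizations as the mode; a tie
containing neutral resolves to neutral; a negative/positive tie without
neutral excludes the image from all analyses. Arousal is a within-subject
median split of 1-9 ratings with ties at the median going to high (sample
median; mean of central order statistics for even counts).

Design matrices are built on a TR-aligned grid (TR = 2 s; 1 s image + 3 s
ISI = 2 TRs per trial; volume indexing 0-based). Each feature regressor is
expanded by a 4-bin FIR filter: an onset at volume v contributes to
volumes v+1..v+4 (2-4, 4-6, 6-8, 8-10 s post onset), truncated at run
ends. Motion nuisance columns, when supplied, enter as-is (6 columns, not
FIR-expanded) and never contribute to validation predictions.

### Gabor features

The image-computed space filters grayscaled, zero-meaned images with a
quadrature Gabor bank: 4 orientations x 5 frequencies (1.5-24
cycles/image). The envelope SD per frequency is `0.375 * image_size /
frequency` pixels (~1-octave bandwidth) and grid centers sit 3 SDs apart,
covering the image; the filter count follows from this rule rather than
being forced to a fixed number, since no SD rule pinning a specific count
is available. Energies are z-scored per filter across the image set.

### Counterbalanced validation sequences

Validation runs present m images in a Type-1 Index-1 sequence of length
m^2 + 1 in which every ordered pair of conditions (self-pairs included)
occurs exactly once - an Eulerian circuit on the complete digraph with
self-loops, built by Hierholzer's algorithm with a seeded RNG choosing
among unused edges.

## Preprocessing

Fixed stage order, operating on voxel x time matrices per run:

1. **Bad volumes.** The scaled mean-square successive difference
   (voxel-mean squared difference between consecutive volumes over the
   run's grand-mean signal) flags both volumes of any transition strictly
   above 10; flagged volumes are replaced by the average of the nearest
   good neighbor on each side (single neighbor at run edges).
2. **Image-on/off regression.** A per-volume stimulus-present indicator,
   FIR-expanded to 4 bins, is regressed out of each voxel (concatenated
   runs). Per-run intercepts are fitted jointly so the signal baseline
   cannot leak into the on/off coefficients - without them, projecting a
   ~100-unit baseline onto 0/1 columns injects a stimulus-grid artifact
   into every voxel.
3. **Savitzky-Golay detrend.** 120 s window (61 samples at TR 2 s -
   nearest odd count), cubic polynomial, per voxel per run; the smoothed
   trend is subtracted. Runs shorter than the window are an error.
4. **Run demeaning.** Per-voxel per-run mean subtraction (idempotent).

## Encoding model

Ridge regression per voxel on the FIR-expanded design, solved through the
SVD of the design matrix (numerically stable across the entire penalty
grid, and one decomposition serves all grid values). The penalty grid is
`10^linspace(-9, 5, 10)`; only the endpoints and count are prescribed, the
spacing is a design choice. A single lambda is shared across voxels so
weights stay on a common scale for the tuning-space PCA: run-blocked
10-fold cross-validation concatenates the held-out predictions of each
fold into a full-series prediction, and the lambda maximizing the mean
per-voxel correlation wins; the final weights are refit on all runs.
Nuisance columns are fitted (penalized identically) but stored outside the
feature tensor and excluded from prediction.

Accuracy is the per-voxel Pearson r between predicted and observed
validation series; constant predictions are recorded as r = 0 with a
degeneracy flag and excluded from significance. r converts to t and z
with `t = r sqrt((n-2)/(1-r^2))` and the normal quantile of the Student-t
tail probability, evaluated in log space on |t| with the sign restored so
both tails keep precision.

The low-level-control refit regresses the Gabor model's *out-of-sample*
predictions out of the estimation BOLD: per run-blocked fold, the Gabor
model fit on the training folds predicts the held-out fold, and the
concatenated prediction is subtracted. A single penalty is selected once
on the full estimation set rather than nested per fold - a deliberate
cost/optimism trade-off that leaves the residualization target unchanged.

## Inference

- **Permutation test.** Validation image identities are shuffled without
  replacement (the event grid, and hence temporal structure, is fixed);
  the shuffled feature matrix is FIR-convolved, multiplied by the fitted
  weights and correlated with the observed series. One-tailed
  p = (1 + #{null r >= observed r}) / (1 + n_perm); the +1 keeps p off
  zero. Implementation note: predictions factor as
  `sum_b O_b (F W_b')[perm]` with per-bin onset matrices O_b, so each
  permutation costs four small matmuls.
- **BH-FDR** across voxels at q = 0.05 (statsmodels step-up procedure);
  degenerate voxels (NaN p) never pass.
- **Bootstrap model comparison.** Validation runs are resampled with
  replacement (1000 draws); per draw, per-voxel r is recomputed on the
  concatenated resampled series for both models and the proportion of
  masked voxels with r_A > r_B recorded, ties counting 0.5 (unbiased
  under the null). z = (mean proportion - 0.5) / SD of the bootstrap
  distribution (that SD *is* the standard error of the observed
  proportion); two-tailed normal p.

## Tuning-space PCA

Peak-HRF weights are the mean of the 4-6 s and 6-8 s FIR bins per
feature, with Plants/Vehicles columns dropped when present. Non-centered
PCA is the SVD of the raw voxel x feature matrix: loadings are right
singular vectors (sign-fixed so each component's largest-magnitude loading
is positive), scores are projections, variance fractions are squared
singular values over the total sum of squares. Column means are *not*
removed, so a shared mean tuning direction can surface as a component.

**Jackknife component test.** One weight matrix per leave-one-run-out
refit (Gram-matrix downdating makes each refit a single solve). For
component k, each replicate contributes the difference between the
variance fraction of its own k-th weight PC and the fraction of its sum of
squares captured by the fixed k-th stimulus-feature PC loading (from
non-centered PCA of the image x feature matrices). The jackknife SE over
replicates gives a one-tailed t test (n-1 df); testing stops at the first
non-significant component; reported p values are floored at 0.03, the
test's stated minimum. The "variance explained by the stimulus PC" is
operationalized as the projection capture on the weight matrix - this
makes the two quantities commensurable where the alternative readings do
not. Calibration (verified by simulation, see the validation battery):
with weight replicates that are pure noise with the stimulus covariance,
component 1 is not significant; with 3 planted dimensions at SNR 2 on a
20-run x 28-image structure with 200 voxels, exactly 3 components are
retained in ~90% of studies. At much smaller scales the test over-retains,
because the ridge-shaped noise floor of fitted weights exceeds the
stimulus-PC capture - a known limitation of this operationalization.

**Matching and consistency.** Subject PCs are matched to group PCs by
highest absolute loading correlation; conflicts go to the subject PC
closest in ordering (recursively), so the output is always a permutation.
Leave-one-subject-out consistency correlates each subject's top-3
loadings with the top-3 of a group PCA excluding them, with significance
from shuffling the group loading entries (default 10,000 permutations,
floored at 1/(n+1)) alongside a parametric t approximation - the
permutation floor alone cannot express very small p values.

**Theoretical dimensions.** Seven feature-length vectors: a 0-3 animacy
scale (humans 3, other mammals 2, other vertebrates/invertebrates 1,
inanimate 0), binary animacy, human presence, and valence (-1/0/+1) and
arousal (0/1) restricted to animate or inanimate features; entries outside
a restricted dimension's partition carry the partition mean, removing
their influence on the correlation. SE features contribute through their
stored modal valence/arousal, computed across subjects from the images
carrying each flag (synthetic defaults are used when no rating data
exist). Dimension-loading correlations get feature-resampling bootstrap
SDs, 95% percentile CIs and one-tailed p values (5000 draws).

## Behavioral prediction

Rater selections over a 25-behavior taxonomy aggregate to per-image
selection proportions (selections over distinct raters); behaviors with
fewer than 1% of all responses (strict) are dropped. Images project into
a model's tuning space as feature-vector x loading inner products (capped
at 21 components; 6 for ValenceArousal).

Leave-one-image-out OLS predicts each behavior's proportion from the
first n PC scores; residuals use the closed-form PRESS identity
e/(1 - h). R-squared is pooled across behaviors (summed squared errors
over summed per-behavior-centered total variance) - pooling matches the
"summed across iterations" aggregation and weights behaviors by their
variance; per-behavior averaging is the alternative and is deliberately
not the default. The curve is scaled by the explainable-variance ceiling:
split-half inter-rater consistency (random half-splits of each image's
raters, per-behavior-centered pooled correlation, Spearman-Brown
corrected, averaged over 100 splits). The split-half estimator is a
choice; the ceiling concept does not come with a formula. Percentile
bootstrap CIs resample images (1000 draws).

The approach (15) / avoidance (7) / passive (3) partition ships as a
documented config default: the passive set is the three responses
requiring no explicit action, the avoidance set the seven
retreat/defend/avoid responses; any partition can be supplied.

## Synthetic studies

The generator reproduces the experiment's structure, not scanner physics:

- **Stimuli/events.** Desk scale: 6 estimation runs x 21 images x 2
  presentations (42 stimulus trials + 6 null trials = 48 slots, nulls
  exactly every 8th slot) and 2 validation runs of 9 images x 9
  presentations in a Type-1 Index-1 sequence; trials occupy 2 TRs, runs
  get a 5-volume tail. Stimulus trials per run must divide into blocks of
  7 so the null-every-8th rule is exact; the full-scale flag uses 30 x 49
  and 20 validation runs. Categories are uniform; valence probabilities
  (0.3, 0.4, 0.3); arousal p(high) = 0.5; SE flags attach to compatible
  category/valence contexts with probability 0.25.
- **Tuning.** Three planted orthonormal dimensions - QR-orthonormalized
  animacy, animate-valence and animate-arousal theoretical vectors - with
  voxel scores scaled by (1.0, 0.7, 0.5); 80% of voxels are tuned (the
  anatomical-ROI stand-in), untuned voxels are exact zeros; tuning noise
  SD 0.05 on tuned voxels; the FIR-bin profile (0.5, 1, 1, 0.3) peaks at
  the 4-8 s bins.
- **BOLD.** design x weights + noise scaled per voxel to the target SNR
  (variance ratio). Noise is 70% white / 30% AR(1) (coefficient 0.3,
  unit-variance normalized); cosine drift (160 s and 288 s periods,
  beyond the SG window) and a constant baseline of 100 ride on top,
  outside the SNR accounting since detrending and demeaning remove them.
  With white-only noise, true-weight predictions correlate with the
  observation at sqrt(SNR/(1+SNR)) - a closed-form check used in tests.
- **Raters.** 9 of 49 workers per image select behaviors by independent
  Bernoulli draws. The default logistic link centers the selection rate
  on 2 of 25 behaviors per rater (the intercept is calibrated so the mean
  probability hits the target despite the spread of the linear
  predictor). The linear link - used when the validation question is
  whether a linear readout recovers linearly generated behavior - sets
  P = 0.3 + 0.1 x (standardized planted-dimension predictor), clipped
  only in the extreme tails (<1% of entries), accepting a higher
  selection rate in exchange for exact linearity. Raters who select
  nothing are recorded with an empty selection so proportion denominators
  stay unbiased. The analytic explainable-variance ceiling implied by the
  generating probabilities is
  `sum_b var(P_b) / (sum_b var(P_b) + sum_b mean(P_b(1-P_b))/9)`.

What passing tests show: the estimators recover exactly the structure
they assume, at the stated scales. What they do not show: robustness to
hemodynamic nonlinearity, spatially correlated voxel noise, rater
non-independence, or feature spaces whose true tuning is not low-rank -
none of which the generator emulates.

## Validation battery (problem sizes)

The acceptance script and `tests/test_acceptance.py` run, per seed:

- ridge vs normal-equations closed form: 12 random systems up to 50
  columns across the full lambda grid;
- permutation-p uniformity: 200 signal-free voxels, 1000 permutations,
  KS against Uniform(0,1);
- empirical FDR: 500 batches of 80 uniform nulls + 20 strong signals;
- weight recovery: SNR 1, 500 voxels, 30 runs x 28 images (~4200
  estimation volumes - the 576-column design needs several thousand rows
  to be identified);
- tuning-dimension recovery and jackknife retention: 50 studies at SNR 2,
  20 runs x 28 images, 200 voxels;
- behavioral recovery: one study with linear rater probabilities at SNR 2
  (30 runs x 28 images, 200 voxels), LOOCV curve vs the analytic ceiling;
- bootstrap comparison: 50 power studies (true vs half-ablated model,
  SNR 1) and 100 exchangeable-null studies.

These sizes were chosen once as the smallest structures at which the
estimators are well-identified; the whole battery completes in a few
minutes on one CPU.

## Known limitations

- The jackknife component test's calibration degrades at small voxel or
  run counts (over-retention), as discussed above.
- Ridge weights for unseen features (category x affect cells never shown)
  shrink to zero; desk-scale studies leave ~35% of CSVA cells unseen, so
  weight-recovery correlations are bounded away from 1 there.
- The explainable-variance ceiling assumes exchangeable raters; real
  rater pools are heterogeneous.
- Degenerate (constant-prediction) voxels are excluded from significance
  rather than modeled.
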