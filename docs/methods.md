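# Methods

This note documents the models, conventions and design choices behind
`tntdecode`, in the order the pipeline runs.

## Data model and conventions

Epochs are `trials × channels × time` arrays in microvolts, time in
milliseconds relative to cue onset (−1000…3500 ms at 250 Hz in the
default design). **Every time window in the package is half-open
`[start, end)`**: the sample at `start` belongs to the window, the
sample at `end` does not. The 61 analysis channels are the 10-5
template positions of a 64-channel cap minus the mastoids (M1/M2) and
the online reference (CPz); the ground (AFz) and EOG are never data
channels. The packaged montage CSV carries 3-D template positions; the
2-D projection used for topographies and triangulation is azimuthal
equidistant about the best-fit sphere center of the electrode cloud.

## Synthetic Think/No-Think generator

The generator is a first-class, fully tested component. Its defaults
encode the task design: 12 Think and 12 No-Think items × 10 repetitions,
6 Perceptual Baseline items × 10 repetitions, per participant.

Planted signals, all scaling unit-norm spatial patterns:

* **Cue pattern** (every condition): item-specific, ≥ 70% (by squared
  weight; 85% exactly by construction) occipital, active 0–500 ms under
  a Hann envelope with a 6 Hz theta carrier.
* **Scene pattern**: item-specific, distributed over frontal–parietal–
  occipital channels, active 500–3000 ms under a Hann envelope with a
  10 Hz alpha carrier; gain 1 in Think, `1 − suppression` in No-Think,
  0 in Perceptual Baseline.
* **Condition theta burst**: frontocentral, 200–400 ms, No-Think only —
  the early control signature the univariate theta contrast detects.
* **Ongoing posterior alpha** at 500–3000 ms, random phase per trial,
  amplitude reduced by `alpha_mod` in No-Think (the sustained alpha
  suppression effect; a power effect, not an evoked one).

Two modeling choices deserve explanation. First, each item's
oscillatory signal is a **rotating source**: a cosine on the item's
primary pattern plus a sine on a partner pattern obtained by a fixed
orthogonal rotation (block-wise within the region and its complement,
so regional concentration and all pairwise item distances are exactly
preserved). A single phase-locked sinusoid would make an item invisible
at timepoints near its carrier's zero crossings; the quadrature pair
keeps the item-specific signal subspace at constant envelope while
remaining narrowband. Second, 40% of the item-signal energy is a slow
evoked deflection (the envelope itself on the primary pattern): real
evoked responses carry both slow and oscillatory components, and the
slow part is what survives the time-window averaging used by the
searchlight and ERP measures.

Item patterns mix coordinates in a 4-dimensional shared basis with an
item-unique component (weight 0.3). The latent structure gives the item
set a wide similarity geometry — as real stimulus sets have — which is
what the subjective raters judge and what RSA must recover; i.i.d.
patterns would make all pairwise distances nearly equal and
representational geometry untrackable. The unique component keeps the
patterns linearly independent.

Noise is Gaussian, shaped to a `1/f` amplitude spectrum per channel and
then mixed across channels with a distance-based Gaussian kernel
(row-normalized, length scale 3 cm) as a minimal stand-in for volume
conduction; the mixing reduces the per-channel standard deviation from
the nominal `noise_sd` (8 µV) to ≈ 3 µV, and makes the noise spatially
low-rank — the property that makes the PCA step meaningful. Default
signal amplitudes (8 µV cue/scene before quadrature split) were
calibrated once so that the pipeline's qualitative output matches the
phenomenon the analysis targets — early decoding everywhere, late
decoding only under retrieval — at realistic desk-scale sample sizes;
they are a calibration, not ground truth, and single-trial SNR of real
recordings is not claimed.

Behavior: each participant's Baseline-minus-No-Think Detail deficit is
`a + b·(true suppression score) + noise` with `(a, b)` solved so the
population standardized mean difference equals `forgetting_dz` (default
0.34) and the deficit–suppression correlation is 0.6. Identification
and Gist are clipped monotone transforms. Subjective ratings: each
rater's item × item matrix is a noisy monotone transform of the
cue-pattern (perceptual) or scene-pattern (conceptual) distances onto
the 1–9 similarity scale (9 = extremely similar); ratings are
continuous, not integer-rounded, so the noise-free limit is exactly
rank-faithful.

Determinism: every output is a pure function of `(seed,
participant_id)`; derived streams use `default_rng([seed, stream,
id])`.

What the generator does **not** emulate: head-model forward projection,
eye/muscle artifacts, trial-count attrition (available but off by
default), non-stationary noise, inter-item behavioral variability.
Passing tests demonstrate the pipeline's correctness and calibration on
data with the assumed statistical structure — not performance claims
about any real recording.

## Decoding engine

Spatial PCA is fitted per participant on all trials and timepoints
pooled and the top 15 components retained (the covariance-eigenvalue
solver; an input with spatial rank below the requested component count
is an error naming the achievable rank). Fitting before the train/test
split mirrors the standard order of operations in EEG decoding; the
mild optimism this can introduce is documented, and a strict per-fold
refit is available (`decode_timecourse(..., pca_per_fold=k)` on raw
channel features).

Cross-validation: per class, trials are randomly partitioned into
`n_bins` near-equal bins (sizes differ by ≤ 1) and averaged into
sub-ERPs; `n_folds = n_bins` leave-one-bin-out. Condition decoding uses
10 bins/folds, item decoding 3, both with 10 iterations of fresh
binning by default. Features are the ±10 ms average around every 20 ms
grid point (the grid starts at the first sample; both numbers
configurable). Train and test are z-scored per feature with *training*
mean/SD only — verified by a leakage probe that corrupts test folds
with a large constant and must stay at chance on null data. The
classifier is a linear SVM (`C = 1`, liblinear): a single binary
machine for each condition pair (one-vs-one over the three conditions),
one-vs-rest for items with prediction by maximal decision value, which
is also the tie-break (the error-correcting-output-codes convention).
Item mode first matches per-class trial counts to the smallest class.

Every tested sub-ERP's (true class, assigned class) is retained at
every timepoint. These records re-aggregate exactly to the reported
accuracies and are the exchangeable units of the permutation nulls.

Resampled item decoding draws a random subset of items (default 6 of
12) per iteration (default 20 iterations), making Think/No-Think item
accuracies directly comparable with the 6-item Perceptual Baseline.
Empirical chance is the mean accuracy when the same pipeline is run on
the pre-stimulus −500…0 ms baseline, where no task information exists.

Time-frequency decoding wavelet-transforms the PCA component time
series and applies the identical procedure per frequency bin; band
summaries average bins with centers in 4–8 Hz (theta) or 9–12 Hz
(alpha).

## Spectral analysis

Morlet wavelets at 22 geometrically spaced frequencies from 2.8 to
30 Hz (both endpoints included), cycle count linear in frequency from 3
to 7. Samples whose wavelet support extends beyond the epoch are
flagged invalid per frequency and excluded from statistics rather than
zero-padded. Decibel baselining uses the mean power over −500…−200 ms,
taken over trials and window samples per channel × frequency
(condition-pooled) and applied to every trial — the averaged-baseline
convention, chosen for stability over trial-wise baselining.

## Searchlight

Channel neighborhoods come from Delaunay triangulation of the 2-D
projected montage, computed three times — as-is, compressed ×0.5 along
x, compressed ×0.5 along y — with the edge sets merged; the compressed
copies add the near-lattice diagonals a single triangulation of a
regular cap misses. Edges longer than 2× the median length are pruned
(a no-op on the packaged montage). The packaged montage yields
6.49 ± 1.47 neighbors per channel against the conventional ~6.39 ± 1.50
for such caps — the residual ~1.6% difference traces to template
positions and projection details and is reported as achieved rather
than tuned away. Searchlight features are the window-averaged signals
of a center channel plus its neighbors; decoding uses the item scheme
(3 bins, 3 folds, 10 iterations) and the accuracy is assigned to the
center. Paired map contrasts form clusters on the neighbor graph with a
sign-flip permutation null.

## Cluster-based permutation inference

Pointwise t-statistics (paired/one-sample or independent) are
thresholded at the critical t for `cluster_alpha = 0.05` (one- or
two-sided as the test demands, df from the design); contiguous
exceedances — along time, on the time × frequency grid
(4-connectivity), or over the channel graph — form clusters with
summed-t mass. Null distributions follow the three schemes the decoding
design admits: re-assigning trial records to random classes (vs-chance,
one-tailed; implemented as permuting the true labels against the fixed
predictions, once per participant per permutation so the temporal
structure is preserved), shuffling condition membership across the
pooled records of two paired conditions (two-tailed), and shuffling
group labels across participants (two-tailed independent). Correlation
timecourses transform Spearman's rho to `t = rho·sqrt((n−2)/(1−rho²))`
(|rho| = 1 capped with a warning) and permute the variable pairing.
Corrected p is `(b + 1)/(m + 1)` against the max-mass null; for
two-tailed tests each tail's null is evaluated at `alpha/2` (critical
values at the 2.5% / 97.5% points) and the reported p is the two-sided
`2 × tail-p`, so `p ≤ .05` means significance. For 2-D maps, observed
clusters are compared with null clusters of the same rank (k-th largest
vs the null distribution of k-th largests). Statistics are restricted
to 0–3000 ms by default. A timepoint where all participants have
exactly equal values (zero variance) gets t = 0 — a deliberately
conservative treatment of a degenerate column that only occurs with
very coarse accuracy lattices.

## RSA

Rater matrices are averaged element-wise; because the rating scale
anchors 9 at "extremely similar", averaged ratings are converted to
dissimilarity as `10 − rating` (a flag accepts already-dissimilarity
input). Matrices are symmetrized by averaging with the transpose;
diagonals are excluded everywhere. Neural RDMs are the pairwise
item-decoding accuracies per timepoint. The comparison is Spearman's
rho between fixed row-major upper-triangle vectorizations, one-sided
(positive) p-values reported only inside the mask of significant
item-decoding timepoints, uncorrected by design. Pre-stimulus rho
values are computed but should be read as a noise band: with tiny
accuracy variance around chance, rank correlations fluctuate widely.

## Behavioral statistics

Repeated-measures ANOVA delegates to `pingouin.rm_anova` with
Greenhouse–Geisser correction (for k = 3 conditions, epsilon is bounded
in [0.5, 1]); partial eta squared is the effect size. Paired contrasts
report Cohen's `dz = t/sqrt(n)`. The high/low-suppression split ranks
Baseline−No-Think Detail scores (ties and odd n broken by participant
id; first half = low) or uses 1-D k-means with k = 2 and deterministic
multi-start. Brain–behavior correlations are Spearman; memory can be
normalized as `(condition − Baseline)/Baseline`, with a zero baseline
yielding a flagged missing value. Dependent correlations sharing a
variable are compared with the Meng–Rosenthal–Rubin z-test. Power for
paired designs is exact via the noncentral t with noncentrality
`dz·sqrt(n)`.

## Problem sizes used in validation

The packaged validation suite runs everything at desk scale, chosen as
study conditions rather than inherited from any single experiment: null
calibration uses 200 signal-free replicate datasets per permutation
scheme at 200 permutations each (4–6 participants per replicate, coarse
time grids); chance calibration uses 12–20 signal-free participants
with the full design; signal recovery uses three replicate datasets of
5 participants at strong signal amplitudes (10 µV) with 40–150 ms
decoding grids, 2–3 iterations and 200 permutations. The false-positive
band is the binomial 95% interval around 0.05, slightly widened for the
Monte-Carlo granularity of 200-permutation p-values. Full-scale
analyses (20 ms grid, 10 iterations, 1000 permutations) use the same
code paths with different parameters.

## Known limitations

* The generator's noise has no line artifacts, drifts or blinks, and
  its spatial covariance is a simple kernel; absolute accuracies do not
  transfer to real recordings.
* Pooled-PCA before cross-validation can be mildly optimistic; the
  strict mode exists but is slower and not the default, matching common
  practice.
* The vs-chance permutation scheme is slightly conservative when the
  number of classified units per participant is very small (the
  label-shuffled accuracy distribution has thinner tails than the
  cross-validated one); with ≥ 24 units per participant the
  false-positive rate sits inside the binomial band.
* Greenhouse–Geisser is the only sphericity correction implemented.
* `detail` recall scores are modeled as continuous means, not integer
  counts.
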