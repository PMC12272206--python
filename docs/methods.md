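# Methods

## Signal model and phase extraction

Region signals are treated as narrow-band oscillations whose
instantaneous phase carries the connectivity information. Each row of a
region × time matrix is demeaned and converted to its analytic signal
with `scipy.signal.hilbert`; the phase θ(n, t) is the argument, the
amplitude the modulus (kept for diagnostics only). No bandpass filter
is applied by default — broadband phase dynamics are retained — but
`compute_le_series` exposes a `prefilter` hook for users who want one.

The instantaneous coherence matrix is dFC(i, j, t) = cos(θᵢ − θⱼ).
Because cos is even and 2π-periodic, phase wrapping is immaterial;
phases are stored in (−π, π]. The matrix is a Gram matrix of the unit
phasors' real and imaginary parts, hence positive semidefinite with
rank ≤ 2 — which is why a single leading eigenvector captures most of
its variance (the `eigenvalue_share` field reports the fraction).

The first and last timepoints of every run are removed: the discrete
Hilbert transform is a global FFT operation and distorts the window
edges. The trim is fixed at one sample per side and not configurable.

**Known limitation — switch blur.** The same global property means the
analytic signal cannot track an instantaneous phase jump: around every
state switch, phases are blends of the adjacent states over roughly ±3
samples. Away from switches (and exactly, for runs with a single state
and an integer number of carrier cycles in the window) the planted
phase offsets are recovered to machine precision. Consequently,
clustering can recover sample-resolution planted labels exactly only on
switch-free runs; on switching runs the achievable adjusted Rand index
is bounded by the fraction of switch-adjacent samples. This is a
property of the measurement operator, not of the clustering.

## Leading eigenvector and sign convention

The leading eigenvector of each dFC(t) is computed by full symmetric
eigendecomposition (`numpy.linalg.eigh`) — exact rather than iterative,
appropriate for the few-hundred-region regime. Signs after
eigendecomposition are arbitrary, so the vector is oriented with the
coherent majority negative: if strictly more entries are positive than
negative it is negated; on an exact tie the orientation with negative
entry-sum is kept, and a zero sum keeps the solver's orientation. The
positive entries then always delineate the anticoherent minority.

## k-medians state clustering

Pooled LE(t) rows from all runs and subjects are clustered with
Manhattan distance. The update step uses the coordinate-wise *lower*
median (for even member counts, the lower of the two middle order
statistics): any value in the median interval minimizes the L1 cost,
and the lower median keeps medians on the data lattice and makes ties
deterministic. Iteration stops at a label fixpoint or 200 iterations.

Restarts alternate two initializations: distance-weighted seeding
(k-means++ adapted to L1), which converges quickly on separated data,
and uniform random partitions, which reach interleaved optima the
greedy seeds systematically miss. The default is 500 restarts; the test
profile uses 20. For small problems (M ≤ 500 points) each restart's
fixpoint is additionally polished by exact single-point moves with
re-optimized block medians — alternating assignment alone only reaches
Voronoi-consistent fixpoints, and on small adversarial instances the
global optimum's basin can be vanishingly rare; with the refinement the
clusterer matches exhaustive partition enumeration on every tested
instance with M ≤ 12.

Empty clusters are reseeded with the point farthest (L1) from its
current median; reseeds never steal a cluster's sole member and never
claim the same point twice, so exactly k nonempty clusters survive.
States are renumbered by descending pooled occurrence by default, so a
dominant uniform-coherence state receives label 1.

## Reconfiguration metrics

For a labeled run of T′ retained timepoints:

* **occurrence** — fraction of timepoints per state (sums to 1);
* **dwell time** — mean length of uninterrupted visits, in timepoints;
  visits truncated by the run boundary count as complete (no censoring
  correction);
* **transition number** — count of consecutive label changes;
* **transition probabilities** — row-normalized consecutive-pair
  counts including self-transitions; rows with no outgoing pair are
  undefined;
* **transition distances** — mean L1 distance between consecutive
  LE(t), stratified by (from, to) state pair; unobserved pairs
  undefined;
* **idiosyncrasy** — mean L1 distance between the subject's member
  LE(t) and the cohort median of the assigned state, computed against
  full-cohort medians by default (the indexed subject included; a
  leave-one-out variant can be assembled from the primitives).

Undefined values are NaN-masked, excluded from the across-run average,
and — when missing for a subject across all runs — imputed at the
cohort median before PLSC, with counts logged. Median imputation
preserves rank structure, which matters because downstream association
strength is assessed by Spearman correlation. The canonical metric
vector is ordered occurrences, dwells, transition number, transition
probabilities (row-major), transition distances (row-major),
idiosyncrasies: (2k + 1 + k²) + k² + k entries, 91 for k = 6.

## PLSC and resampling inference

Both blocks are preprocessed by per-column OLS confound regression
(age, gender, with intercept) followed by z-scoring (SD with divisor
n − 1). Held-out data always reuse train-fitted coefficients, means and
SDs. The cross-block matrix R = XᵀY/(n − 1) is decomposed by SVD;
scores are X U and Y V, loadings are Pearson correlations of each
column with its own side's score, covariance explained is s²_d / Σs²
(the linear convention s_d / Σs is available), and per-dimension
association strength is the Spearman correlation of the paired scores.
Weight signs are fixed deterministically (largest-|u| entry positive).

* **Permutation test.** Each family's members are dealt into slots
  (order randomized once from the seed); slot b across families forms a
  block containing at most one relative of anyone, and Y rows are
  permuted within blocks only (a both-sides mode permutes X
  independently). Per dimension, p = (1 + #{s*_d ≥ s_d}) / (n_perm + 1);
  no Procrustes realignment of permuted solutions is attempted.
  Permuting one side is covariance-equivalent to permuting both with
  independent permutations; permuting both with a shared row
  permutation would preserve the association and test nothing.
* **Bootstrap.** Whole families are resampled with replacement until at
  least n subjects are drawn; preprocessing and PLSC are refit per
  resample; each resample's dimensions are aligned to the original by
  greedy |dot|-matching of stacked weight vectors with sign correction;
  BR = original loading / SD (ddof = 1) of its bootstrap distribution.
  Zero bootstrap SD yields ±inf and is counted. On resampled data,
  preprocessing is lenient: zero-variance columns become zeros and
  collinear confound draws are handled by least squares rather than
  aborting the resample.
* **Split-half.** Families are dealt into halves balancing subject
  counts (a family larger than half the cohort is rejected). The test
  singular value is u_dᵀ R_test v_d with train weights and train-fitted
  preprocessing applied to the test half; weight similarity is
  |u_train,d · u_test,d| per side, with the test half also fitted.
  Z = mean/SD across splits; the similarity is taken on weight vectors
  because score vectors of disjoint halves index different subjects.
* **Cross-validation.** Families are dealt into folds balancing sizes;
  test subjects are projected with train weights (dimension-aligned to
  the full-data solution); pooled out-of-fold score pairs give the
  out-of-sample Spearman correlation, and their correlation with the
  in-sample scores gives consistency.
* **Variance explained** is 1 − ‖M − PM‖²_F / ‖M‖²_F with P the
  projector onto the score columns; the pipeline reports it for the
  permutation-significant dimensions only, since all min(p, q) scores
  trivially span the smaller block.

Randomness uses one master seed with independent spawned substreams per
procedure, so stages are individually reproducible.

## Shared statistics

Test–retest reliability uses ICC(2,1) — two-way random effects,
absolute agreement, single measurement — computed from the two-way
ANOVA mean squares; ICC(3,1) (consistency) is available by flag. The
ANOVA estimator can undershoot −1 on degenerate small samples, so the
reliability table clamps to [−1, 1]. Sessions default to the mean of
the first and second half of each subject's runs. Benjamini–Hochberg
FDR adjustment wraps `statsmodels.stats.multitest.multipletests`;
Spearman correlation wraps `scipy.stats.spearmanr` with NaN masking for
zero rank variance.

## Synthetic cohort generator

The generator emulates exactly the structure the pipeline assumes, with
every latent recorded:

* k phase-locking patterns over N regions; pattern 1 is uniform
  (all-coherent), the rest carry disjointly drawn anticoherent
  minorities (offset π, minority size = round(fraction · N), strictly
  below N/2; identical nonempty minorities are redrawn);
* region signals sin(2πft + offset_state(t) + perturbation) + Gaussian
  noise, with hidden state labels from a sticky Markov chain started at
  its stationary distribution, one label per sample;
* per-subject *stickiness bias* b (self-transition odds scaled by eᵇ)
  and *idiosyncrasy scale* σ (a fixed per-region phase-perturbation
  vector drawn with SD σ), the two "true reconfiguration parameters";
* families sharing a Gaussian random effect on b (breaking
  exchangeability across families); age (uniform integers 22–36) and
  gender (Bernoulli) with linear effects on both sides;
* behavioral scores = weights · z-scored true parameters + confound
  effects + noise; zero weights give an exact null cohort.

Defaults are n = 200 subjects (one quarter in families of two), 2 runs,
24 regions, 150 timepoints, k = 4 states, carrier 0.1 cycles/sample
(≈ 0.14 Hz at a 0.72 s sampling interval), stay probability 0.95
(mean dwell ≈ 20 samples ≈ 14 s), noise SD 0.3 on unit-amplitude
carriers, idiosyncrasy scale uniform on (0.05, 0.45) rad. The sticky
regime keeps switch-adjacent transform blur (see above) to a small
fraction of samples, the regime in which sample-resolution labels are
meaningfully recoverable. With 150 timepoints the default carrier gives
an integer cycle count, so noiseless switch-free runs are recovered to
machine precision.

What the generator does **not** emulate: hemodynamic convolution,
realistic fMRI noise spectra (1/f, physiological), head motion, spatial
parcel geometry, amplitude dynamics, or graded (non-binary) phase
offsets. Passing tests therefore demonstrate correctness of the
estimators under the stated signal model and calibrated inference under
planted associations — not robustness to the full complexity of real
resting-state data.

A matrix-level generator (`simulate_linked_matrices`) produces the two
PLSC input blocks directly — a standard-normal latent score links
planted variables of both sides, families share an X-side random effect
so nulls stay exact nulls while exchangeability is broken — and is used
for inference calibration at scale (hundreds of replicates), where
simulating timeseries would add nothing but runtime.

## Problem sizes in the test suite

The suite exercises the pipeline at desk scale, chosen so behavior is
measurable with comfortable margins: cohort recovery at 10–16 subjects
and 150–300 timepoints; calibration at 200 null replicates (n = 150,
500 permutations); bootstrap rates over 50 replicates (n = 300, 200
bootstraps); split-half behavior over 5 planted and 20 null replicates
(n = 400, 150–200 splits); the end-to-end run at the full default
design (200 subjects × 2 runs) with test-profile resampling counts
(20 restarts, 500 permutations/bootstraps/splits, 5 folds). The full
profile (500 restarts, 10,000 resamples, 10 folds) is the default for
real analyses.
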