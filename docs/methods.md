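# Methods

This note documents the models, estimators, numerical choices and known
limitations of `twinstates`, and what the synthetic-cohort experiments do
and do not establish.

## Signal preparation

Parcellated source time series (time × region) pass through a fixed order:
linear detrend → zero-phase band-pass → symmetric orthogonalization →
Hilbert envelope → anti-aliased downsampling to 40 samples/s.

- **Band-pass**: 4th-order Butterworth applied forward–backward
  (`sosfiltfilt`, effective order 8). Zero phase preserves envelope timing;
  the five canonical bands (delta 1–3, theta 4–7, alpha 8–12, beta 13–25,
  gamma 30–45 Hz) are defaults.
- **Collinearity screen**: column-pivoted QR on the time × region matrix;
  the trailing `n_exclude` pivots (smallest |R| diagonal) are the most
  collinear regions. `n_exclude` defaults to 0 for synthetic data; 14 is
  the preset matching a 68 → 54-region atlas reduction.
- **Symmetric orthogonalization**: the closest set of mutually orthogonal
  time courses in Frobenius norm, by alternating a polar decomposition
  (optimal orthonormal basis for fixed column magnitudes) with a per-column
  magnitude fit, until the relative change in reconstruction error is below
  `tol` (default 1e-10, max 200 iterations). Columns are demeaned first so
  orthogonality equals zero correlation. Unlike sequential regression-based
  leakage correction the result is independent of region order; the test
  suite verifies it is never farther from the input than the sequential
  alternative. Applied per subject over the full recording.
- **Downsampling**: polyphase resampling (`resample_poly`, `padtype="line"`)
  rather than block averaging, making the anti-aliasing filter explicit.
  DC gain is exact to ~1e-4 (Kaiser design), which is why the DC-preservation
  test uses a 1e-3 tolerance.

## The hidden Markov model

Gaussian observation model with full per-state covariance — each state is a
mean activation vector plus an amplitude-coupling covariance. Envelopes are
z-scored per subject and region, then concatenated; chains restart at
subject boundaries. Inference is expectation–maximization (Baum–Welch) with
scaled forward–backward. The variational-Bayes toolboxes common in this
literature fit the same model class; plain EM was chosen deliberately
because every quantity (log-likelihood, posteriors, M-step) has an
exhaustive-enumeration oracle at small sizes, which the tests exploit.

- Initialization: k-means on a subsample (≤20k samples, 3 inits), sticky
  transition matrix (0.8 self-probability), uniform initial distribution;
  best of `n_restarts` (default 5) by final log-likelihood.
- Convergence: relative log-likelihood change < 1e-5, max 500 iterations;
  the per-iteration log-likelihood is non-decreasing to 1e-8 (tested).
- Covariance conditioning: ridge of 1e-6·trace/R added on Cholesky failure,
  escalated ×10 up to 8 times before erroring.
- Equal-length subject recordings use a batched forward–backward/Viterbi
  that vectorizes the time recursion across subjects (identical results to
  the per-sequence recursions, verified to 1e-10; ~20× faster at cohort
  scale).
- **Canonical state order**: HMM labels are arbitrary, so states are
  relabeled by descending group fractional occupancy (ties: earliest first
  activation). All downstream features are invariant to the initial
  labeling (tested).

FO, TP and dwell times are computed on the hard Viterbi path by default —
transitions are only well-defined on a hard path — with a soft
(posterior-weighted) FO variant available; soft and hard FO agree closely
when posteriors are saturated.

## Features

- **FO**: occupancy fractions (1×K). **TP**: row-normalized transition
  counts (K×K, diagonal included, full K² vector in the multivariate
  phenotype); rows of states never departed from fall back to uniform 1/K
  so the matrix stays row-stochastic, flagged by construction.
- **Subject state FC**: posterior-weighted Pearson correlation per state;
  states with < 10 effective samples are flagged and fall back to the
  subject's static FC.
- **Modularity**: Newman's Q for a fixed ICN partition on the non-negative
  graph (negative FC edges zeroed; classic Q is defined for non-negative
  weights). A signed variant (strength-weighted Q⁺ − Q⁻) sits behind a
  flag. Subject-level state FC is the default input, since heritability
  needs subject values.
- **Cluster FC**: mean FC over a data-driven edge mask, per state. The mask
  comes from edgewise state-ANCOVA F values thresholded at a connection
  density (default 5%; 1–4% available), optionally filtered by NBS
  significance.
- **ICN-pair FC**: block means over all within/between network pairs
  (21 + 7 = 28 entries for seven networks), exploratory.

## State contrasts and NBS

Edgewise ANCOVAs pool subject × state rows (fixed-effects; factor state,
covariates centered age and binary sex) and compute the state-factor F by
extra sum of squares — no repeated-measures error term, so the denominator
df is n·K − K − 2 − 1. NBS: threshold the F matrix at the target density
(ties broken by edge index), take connected components as clusters, and
compare each observed component's edge count against the permutation null
of the maximum component size, permuting state labels within subject
(covariates untouched); p = (1 + #{perm ≥ obs})/(1 + n_perm), so p is never
exactly 0. With very sparse thresholds the discrete component-size
distribution makes the procedure conservative (empirical FWER can sit well
below nominal), which the calibration test tolerates in the safe direction.

## Surrogates and the null origin

Surrogates preserve each subject's static mean and covariance and destroy
temporal ordering: i.i.d. Gaussian draws of the original length (clipped at
zero to remain envelopes). This is the simplest instantiation consistent
with "static covariance preserved, dynamics destroyed". For each of
`n_surrogates` (default 50; tests use 2–8) replicates the HMM is refit,
states re-ordered, features extracted, and the subject-average taken; the
origin is the mean over surrogates. The group-level average defines the
origin by default; a subject-level variant is exposed by flag. Failed
surrogate refits are dropped with a logged warning.

## Heritability screen

Pair similarity = Euclidean distance between feature vectors
(origin-independent). One-way ANCOVA of sibling status on distances with
covariates pair age difference and pair sex; F df = (2, n_pairs − 5);
partial η² = SS_status/(SS_status+SS_err). Bonferroni correction uses the
fixed family of 20 (4 features × 5 bands) regardless of extra exploratory
features. Bayes factors use the BIC approximation
BF01 = exp((BIC_H1 − BIC_H0)/2) — an approximation to a default Bayes
factor, adequate for direction-of-evidence statements. Power analysis uses
the noncentral F with noncentrality f²·n; the minimum detectable f is
found by bisection. A reported effect of η² = 0.021 converts to
f = √(η²/(1−η²)) ≈ 0.147; treating the printed "h² = 0.021" as η² is the
only reading consistent with its printed f = 0.145 equivalence, and the
package adopts it.

## Twin variance components

Phenotype: the subject's distance from the null origin, residualized on age
and sex and scaled to unit variance, so fitted components are fractions.
Likelihood: product of bivariate normal pair densities with common mean and
zygosity-structured covariance. Optimization: L-BFGS-B on the variance
parameters (bounded at 0) plus the mean, 10 restarts from Dirichlet-split
initializations. Unrelated pairs carry zero A, C and D correlations
(individuals from different families). AIC = −2LL + 2·(n_variances + 1).
CIs: delta method on the unconstrained variance parameterization (Hessian
by central differences, parameter covariance 2·H⁻¹), so lower bounds can
cross zero even though estimates cannot — this mirrors the reporting
convention of standard twin-modeling software; a pair-resampling bootstrap
is available by flag. LRTs use the plain χ² reference (3.84 at Δdf = 1)
despite the boundary non-regularity; under a true nested model the χ²
statistic is attenuated toward zero, so the test is conservative for
rejecting the nested model (verified by simulation: the null 95th
percentile falls in [2.5, 5.5]). The full ACE or ADE family is selected by
the twin-correlation pattern (ADE iff r_DZ < r_MZ/2) and retained unless a
nested model is preferable; since a nested model can never fit better in
likelihood, the full model is the reported default alongside all nested
fits.

## Synthetic twin cohorts

Per subject, a latent K-vector is built from A/C/D/E components with the
classic twin correlations, giving unit variance and within-pair correlation
a²·r_A + c²·r_C + d²·r_D (tested against the closed forms). Latent k
perturbs row k of the base transition logits along a fixed zero-sum
direction, normalized by the local softmax Jacobian so one latent unit
moves each row by about `effect_scale` in probability space regardless of
row stickiness; `effect_scale = 0` reproduces the base matrix exactly. The
generative link between genotype and dynamics is an artifact design choice,
not a biological claim. Emission parameters are shared across subjects by
default (only dynamics are heritable); a flag makes state means heritable
to probe the spatial-feature null. Envelopes are generated directly in
envelope space (state-conditional Gaussian draws shifted by +8 and clipped
at zero; downstream z-scoring removes the shift) for speed; a narrowband
oscillation mode exercising the filtering/Hilbert path is not the default.
Ages are uniform on 23–40 years per pair (members within 1 year, except a
configurable mismatch fraction, default 0); sexes are assigned 50/50 at
pair level. One global seed fans out to per-subject substreams by CRC-32
hashing of the subject id, so outputs are bit-reproducible and independent
of iteration order.

Defaults mirror the target design: 206 MZ + 112 DZ + 145 unrelated pairs
(463 pairs, 926 subjects), 54 regions, 6 states, 40 samples/s, sticky
transitions with 0.9 self-probability (mean dwell 250 ms — subsecond, as in
the empirical phenomenon).

### What the dissociation experiment shows — and a measured estimation leak

The acceptance experiment generates cohorts of 132 pairs (60/36/36) with
a² = 0.7 on the dynamics latents, `effect_scale` 0.35, K = 3 states over
8 regions, 120 s recordings, and **covariance-dominated states**
(`mean_scale` 0.5, stickiness 0.85). Sizes are scaled down from the
463-pair design so that twenty replicate cohorts run end to end in
minutes; the effect size is correspondingly larger than a realistic h² of
0.4–0.6 would produce at full scale, because Bonferroni-corrected power at
132 pairs demands it.

During design we measured a genuine estimation pathway by which heritable
*dynamics* leak into subject-level *spatial* features: decoded state masks
differ between subjects as a function of their dynamics, and when state
means are far apart, even a fraction of a percent of misassigned boundary
samples injects mean-offset outliers into the state FC whose magnitude
grows with the mean separation — making modularity and cluster-FC
spuriously heritable. With oracle (ground-truth) masks the spatial null
holds cleanly, confirming the effect is estimation-side, not generative.
With covariance-dominated states (small mean separation, as appropriate
for amplitude-coupling-defined states) the contamination term is small and
the spatial screen is null at the corrected level while FO/TP remain
strongly significant — the qualitative temporal/spatial dissociation the
pipeline is designed to exhibit. Passing this experiment therefore shows
the pipeline detects planted dynamic heritability and does not manufacture
spatial heritability *in this regime*; it does not bound the leak for
strongly mean-separated states, which remains a known limitation of
subject-level state-FC features generally.

## Problem sizes used in tests

Exhaustive HMM oracles: T ≤ 8, K ≤ 3. Planted-recovery fits: T = 20k–60k
samples, R ≤ 6. NBS calibration: 200 null replicates, 20 subjects, 20
regions, 100 permutations each. Twin-model recovery: 100 replicates of
5,000 pairs. Dissociation: 20 replicate cohorts of 264 subjects. Surrogate
counts in tests are 2–8 (the analysis default is 50). These sizes were
chosen so the full suite runs on a single CPU in well under half an hour
while keeping every statistical check at its stated threshold.

## Known limitations

- EM finds local optima; restarts mitigate but do not guarantee the global
  maximum. Canonical ordering makes runs comparable, not identical across
  different restart seeds.
- The pooled fixed-effects ANCOVA ignores within-subject correlation
  across states; its denominator df convention is documented rather than
  matched to any particular historical report.
- The BIC Bayes factor and delta-method CIs are asymptotic approximations.
- The surrogate model destroys *all* temporal structure (including
  autocorrelation within states), which is the intended null but is
  stronger than, e.g., phase randomization.
- Subject-level spatial state-FC features inherit a dynamics-dependent
  estimation bias in strongly mean-separated regimes (see above).
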