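# Methods

`cafrisk` implements a complete pipeline for building and explaining a
clinical risk model of concern about falling (CAF) in knee osteoarthritis
(KOA): a swarm-intelligence optimizer, a synchronous wrapper that selects
features and tunes hyperparameters jointly, four base learners behind one
contract, an evaluation stack, an in-house Shapley engine, baseline-table
statistics, and a synthetic cohort generator.  This note records the models,
the defaults that matter, and the design choices that were genuinely open.

## The optimizer (GKSO and IGKSO)

GKSO is a population minimizer over a box, built from three predatory
behaviours chosen per individual per iteration with an exploration weight
p = 1 − t/T:

- **hunting drive** (probability p): `x' = x + r1·(best − x) + p·r2·(xa − xb)`
  with two random peers `xa, xb` — a differential move toward the prey;
- **foraging contraction** (probability 1 − p):
  `x' = best − A·|2·r·best − x|` with `A ~ U(−a, a)`, `a = max(2p, 0.2)` —
  a per-dimension attention envelope around the prey that shrinks as the run
  progresses but keeps a floor of perturbation noise so the shoal never
  freezes;
- **self-protection** (probability 0.1): a random subset of dimensions
  (30% each) is re-randomised uniformly; the jump is taken unconditionally,
  acting as a diversity-preserving restart.

All other moves are accepted greedily (only on improvement), and the global
best is tracked over everything evaluated, so the convergence curve is
monotone by construction.  The baseline's phase equations are this package's
own reconstruction of the published behavioural description; they are
isolated behind `gkso_step` so that the two IGKSO additions are testable
independently.

IGKSO adds exactly two ingredients:

1. **Bernoulli chaotic initialization.**  Initial coordinates come from
   orbits of the piecewise-linear Bernoulli shift map
   `x → x/(1−λ)` for `x ≤ 1−λ`, else `(x−(1−λ))/λ`, with λ = 0.4, one orbit
   per individual, ≥ 20 burn-in steps.  Consecutive orbit values are
   autocorrelated (≈ 0.5), so every 10th value is taken per coordinate; the
   marginals are uniform and the draw retains the mixing character of the
   map (the orbit's empirical deciles are all occupied at n = 1000).
2. **Spiral-flight mutation.**  With probability 0.2 per individual per
   iteration, a logarithmic-spiral move
   `x' = |best − x|·e^{b·l}·cos(2πl) + best`, `l ~ U(−1, 1)`, `b = 1`, is
   proposed and evaluated.  Acceptance is greedy, with one refinement:
   mutants always challenge the elitist archive, but may replace their
   parent individual only in the final quarter of the run.  Relocating
   individuals toward the incumbent basin earlier (or feeding mutant wins
   back into the swarm's guiding best mid-exploration) measurably collapses
   diversity and makes the "improved" variant worse than the baseline on
   multimodal benchmarks — this gating is what turns the spiral into a pure
   intensifier.

Boundary handling is clamping.  Non-finite objective values trigger a
uniform reset of the offending individual.  One `numpy` SeedSequence fans
out into separate init / dynamics / mutation streams, so runs are bit-for-bit
reproducible and the two variants share their dynamics stream.

### Benchmark validation

The 23-function suite is the classic unimodal/multimodal collection
(sphere, Schwefel variants, Rosenbrock, step, quartic-with-noise, Schwefel
2.26, Rastrigin, Ackley, Griewank, two penalized functions, Shekel
foxholes, Kowalik, six-hump camel, Branin, Goldstein–Price, Hartman 3/6,
Shekel 5/7/10) at canonical dimensions (30 for F1–F13) and bounds.  The
quartic function's additive noise is derived from a hash of the evaluated
position plus a seed, making it a pure function — protocols stay
reproducible without threading a noise stream through the optimizer.  The
comparison protocol (population 30, 200 iterations, mean of best-so-far
curves over repetitions, repetition r seeded `base_seed + r`) defaults to
30 repetitions, and the full depth matters: Rastrigin final values spread
widely between repetitions (sd ≈ 25 around means ≈ 70), so the variants'
true ~10-point margin there is measured unreliably by shallower runs — a
10-repetition mean comparison flips sign about one time in five purely by
sampling noise.

## Synchronous feature/hyperparameter optimization

One optimizer individual lives in `[0,1]^D`, `D = n_features + n_hyper`.
Feature j is selected iff coordinate j ≥ 0.5 (a fixed-threshold transfer;
if nothing passes, the largest coordinate is selected).  Hyperparameters
decode per kind: affine for continuous, `10^(affine in log10)` for
log-uniform, rounded affine for integers, index `floor(u·K)` (capped) for
categoricals.  Conditional parameters (SVM polynomial degree) are decoded
regardless and flagged inactive when their gate does not hold.

Fitness is stratified 5-fold cross-validated mean F1 at threshold 0.5,
averaged over **3 independently seeded partitions**, minus a parsimony
penalty `λ·n_selected/n_features` with **λ = 0.025 by default**.  Both
choices address the same measured pathology: a single fixed CV partition is
near-flat in irrelevant features — toggling one noise feature moves the
partition F1 by a few thousandths in either direction, and *raises* it in
roughly a quarter of cases (up to +0.007) — so an unpenalized
single-partition objective rewards noise features often enough that no
optimizer can reject them reliably.  λ is set so that the per-feature
penalty (λ/n_features ≈ 0.002) matches the median absolute single-feature
fluctuation of the objective — a noise-floor regularizer, deliberately an
order of magnitude below a genuinely informative feature's contribution
(~0.02) — and the partition averaging shrinks that fluctuation by ≈ √3 so
the penalty separates signal from noise features instead of sitting inside
the noise band.  The partition seeds derive from a CV seed independent of
the optimizer stream, so fitness is a fixed deterministic function within
a run; candidate fitness values are memoized on (mask, hyperparameters).

The train/test split rounds `n_class·(1−fraction)` per class: a 541-row
cohort with a 360/181 outcome split at fraction 0.2 gives exactly 433
training and 108 testing rows.

## Base learners

Logistic regression (liblinear; L1/L2 via `l1_ratio`), a back-propagation
MLP (architectures (50), (100), (50,50); 500 epochs, no early stopping),
an SVM (linear/RBF/poly; the score is the decision function through a
logistic — a monotone score in [0,1], avoiding the cost and opacity of
inner-CV Platt scaling), and XGBoost (100 trees, `hist`).  Hyperparameter
values are validated against the registry ranges before any training.
Continuous features are z-scored with statistics from the training rows
only, categoricals one-hot encoded, binaries passed through.  A purely
numeric matrix takes a pandas-free fast path (the wrapper search trains
thousands of models).

## Evaluation stack

Confusion metrics (PRE/SEN/SPE/ACC/F1) use inclusive thresholding
(`score ≥ t`) and return 0 with an explicit degenerate flag on empty
denominators.  ROC-AUC is the Mann–Whitney concordance with ties counted ½;
PR-AUC is average precision (step integration — trapezoidal interpolation
is optimistic).  Decision-curve net benefit is
`TP/N − FP/N·pt/(1−pt)` on a default grid 0.01…0.99 (step 0.01), with
treat-all and treat-none references and a helper for the 22–76% band in
which the deployed model is expected to be clinically useful.  Calibration
uses 10 equal-width bins (last bin closed) plus the Brier score.

## Shapley attribution

The value function is the marginal (interventional) expectation over a
background sample (default 100 seeded training rows): `v(S)` keeps the
explained row's features in S and averages the model output over background
substitutions of the complement.  Exact mode enumerates all `2^d`
coalitions (d ≤ 12) with the classical weights; efficiency
(`base + Σφ = prediction`) then holds to 1e-9 and the dummy and symmetry
axioms hold to machine precision.  Sampled mode averages marginal
contributions over seeded uniform permutations with coalition-value
memoization; per-feature Monte-Carlo standard errors shrink as 1/√n_perm,
and efficiency is exact by telescoping.  Attributions are computed on the
probability scale.  Pairwise interaction tensors are out of scope; the
interaction views are served as dependence scatter data (feature value, φ,
moderator value).

## Baseline statistics

Continuous group comparisons use the pooled-variance (Student) t-test —
from raw samples or directly from published (mean, SD, n) summaries — and
categorical comparisons the uncorrected Pearson χ².  Both choices were
verified by recomputation against the published cohort tables: all 16
printed t statistics match to <0.001 and six of the printed χ² values match
at printed precision.  Four published χ² entries do not recompute from
their own printed counts under any standard variant (employment 0.011 vs
0.031, occupation 0.004 vs 0.054, living mode 0.037 vs 0.052, one KL
comparison 0.327 vs 0.348); the first two are excluded from the
reproduction set, the latter two fall inside the ±0.05 reproduction
tolerance and are kept.

## Synthetic cohorts

The generator matches the published *marginals* of the study population:
per-outcome-group Gaussians for the eight features with published group
moments (age, BMI, sex, knee extensor moment, TUG time, KL grade, WOMAC
pain, HADS anxiety), and whole-cohort (training-set) distributions, applied
group-independently, for the rest (disease duration, gait speed, WOMAC
stiffness/function, employment, education, living mode, MRI findings).
Continuous draws are rejection-resampled into plausibility ranges
(e.g. TUG > 0) rather than clipped, so moments stay on target.  Marginals
do not determine the joint distribution: features are independent within a
group by default, and an optional Gaussian copula over the continuous block
is exposed for callers who want correlation — no unpublished structure is
baked in.  Consequently the generated cohorts do **not** reproduce the real
cohort's predictive strength (the published F1/AUC/Brier of the fitted
model are properties of the real joint distribution); what passing tests
show is that the machinery — optimizer, wrapper, learners, metrics,
explanations — behaves correctly on data with known structure, not that the
clinical effect sizes are recoverable from marginals.

Generator fidelity is checked by scaling the cohort ×10, re-estimating the
group moments, and evaluating the pooled t at the published nominal group
sizes (360/181): each recomputed |t| must fall within 15% of the printed
value (a raw t on the scaled cohort would grow by √10 and be incomparable).
The two categorical rows are checked for direction and significance only: a
χ² statistic is quadratic in the group contrast, and at this scale its
sampling error (≈20–30% relative) swamps a 15% band.

The planted-signal bed draws Gaussian features with a mean shift of
`effect_size` SD between classes for informative features, none for noise
features, at a 2:1 class balance mirroring the cohort.

## Problem sizes in the shipped checks

The acceptance checks run the benchmark comparison at the full 30
repetitions, the feature-recovery experiment at 10 runs (n = 400, 5 + 10
features, LR, population 20, 40 iterations), and generator fidelity at
scale ×10 — sizes chosen so the full validation completes comfortably on a
single CPU while keeping the statistical checks meaningful.

## Known limitations

- The GKSO baseline is a behavioural reconstruction, not a transcription of
  the original phase equations; conclusions about IGKSO-vs-GKSO margins are
  conditional on it.
- The published final XGBoost configuration and the eight selected clinical
  features ship as documented constants (`PUBLISHED_XGB_HYPERPARAMS`,
  `PUBLISHED_SELECTED_FEATURES`); they cannot be re-derived without the
  original patient records.
- Model files are configuration records (learner, hyperparameters,
  features, seed, training-data path); evaluation and explanation re-fit
  deterministically rather than deserializing fitted state.
- SVM scores are monotone, not calibrated; Brier scores for the SVM should
  be read accordingly.
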