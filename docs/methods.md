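# Methods

## The model

`irgps` implements a rank-based prognostic model for overall survival
built from *immune-related gene pairs* (IRGPs). For an ordered pair of
genes (a, b) and a sample s with expression matrix x, the pair score is
the binary indicator

    s_k(s) = 1[ x_{a_k, s} > x_{b_k, s} ]      (strict inequality)

and the risk score is the linear predictor of a Cox proportional-hazards
model over those indicators,

    r(s) = Σ_k β_k · s_k(s).

Because r depends on the data only through *within-sample* orderings, it
is invariant under any strictly increasing transformation applied to a
sample's expression vector. That is the core claim of the approach: a
signature fitted on one platform (e.g. RNA-seq FPKM) can be applied to
another (e.g. array intensities) with no normalization, batch
correction, or cross-sample standardization. The package tests this
claim literally: every rank-based output must be *bit-identical* under
per-sample monotone distortions.

Ties score 0 ("otherwise zero"). This is consequential: FPKM matrices
carry a point mass of exact zeros, so a pair of two unexpressed genes
scores 0, not ½. The synthetic generator plants a 5% zero mass by
default so this path is always exercised.

## Signature construction

Given an expression matrix (genes × samples), a survival table and
optionally an immune-gene list, `fit_workflow` runs the funnel:

1. **Gene filters.** Probe-level duplicates are collapsed by arithmetic
   mean; genes are kept when mean expression > 0 and unscaled MAD
   (median(|x − median(x)|), no 1.4826 consistency factor) > 0.5. Both
   thresholds are configurable.
2. **Pair scoring.** All ordered pairs, one orientation per unordered
   pair by default — the reverse orientation is redundant on tie-free
   data by antisymmetry, and a signature coefficient absorbs orientation.
3. **Near-constant pair removal.** A pair whose majority score value
   occupies strictly more than 90% of samples is dropped (it cannot
   stratify and would destabilise the lasso).
4. **Candidate screen.** Each surviving pair is tested univariately
   against survival with a Cox fit (Efron ties) *and* a two-group
   log-rank test; a candidate must have both p < 1e-4 (the AND reading
   is conservative; an OR mode exists behind a flag). The screen is a
   bespoke fully-vectorised implementation — closed-form Newton updates
   for a binary covariate across all pairs simultaneously — because
   per-pair model objects are orders of magnitude too slow for the
   tens of thousands of pairs a cohort produces. It is tested against
   lifelines and against a symbolic (sympy) maximiser of the Efron
   partial likelihood. Under complete separation the Wald statistic
   degenerates (information → 0), so capped fits report the score test
   at β = 0 instead; null calibration is unaffected.
5. **Consensus lasso.** "Many random cycles" of 10-fold cross-validated
   L1-penalized Cox over the candidates (scikit-survival's
   coordinate-descent path solver; held-out Breslow partial likelihood
   as the CV criterion, computed in-package). A pair is kept when its
   coefficient is nonzero at the cycle's CV-optimal penalty in ≥ 50% of
   cycles; final coefficients come from one lasso fit at the median
   CV-optimal penalty restricted to the kept pairs. Repetition with
   fresh fold assignments stabilises the lasso's arbitrary choices
   among highly correlated pairs (pairs sharing a gene are strongly
   dependent) and yields a small signature. Cycle count (default 1000;
   100 in the bundled analyses — the consensus is already stable there),
   fold count, consensus fraction, and the penalty rule are knobs.
   The CV optimum (not a 1-SE rule) is used: with a consensus vote on
   top, the extra parsimony of 1-SE adds nothing but another knob.
6. **Cutoff.** Time-dependent ROC at 36 months using the Kaplan–Meier
   cumulative/dynamic estimator; the operating cutoff maximises
   sensitivity + specificity (Youden), ties toward the smaller
   threshold. Group assignment is high iff r > cutoff, so a score
   exactly at the cutoff is low-risk (the boundary rule is not dictated
   by the construction; this choice is documented rather than implied).

## Time-dependent ROC

At horizon t, cases are subjects with an observed event by t, controls
subjects event-free at t. With censoring, case/control membership is
unknown for some subjects, so sensitivity and specificity are estimated
with the Kaplan–Meier plug-in (S the product-limit estimator):

    sens(c) = [1 − S(t | X > c)] P̂(X > c) / [1 − S(t)]
    spec(c) =      S(t | X ≤ c) P̂(X ≤ c) /      S(t)

This estimator is parameter-free and exactly checkable against
hand-computed KM products, which is why it is preferred here over
nearest-neighbour smoothing variants (no smoothing span to choose; the
cost is that the plug-in can leave [0, 1] on small strata — values are
clipped with a warning). AUC is the trapezoid over the threshold-ordered
(FPR, TPR) path; integrating in path order rather than sorted order
keeps nominally-vertical staircase segments vertical despite
floating-point jitter in 1 − spec.

## Survival evaluation

Group evaluation delegates to lifelines: k-sample log-rank,
Kaplan–Meier curves, restricted mean survival time (area under the KM
curve to τ, reported per group with a high/low ratio), and Cox
regression with the Efron tie correction — the right default for
month-resolution follow-up, where ties are heavy. Confidence intervals
are exp(coef ± 1.96·SE); ordinal clinical covariates (stage, T, N,
Clark level) enter as numeric scores; multivariate models use complete
cases (no imputation). The risk factor enters as the continuous score
by default, with a flag for the binary group. Mutation-stratified
subgroup analysis repeats group assignment, log-rank and Cox within
each stratum of a binary flag; degenerate strata (one group empty, or
no events) report NA with a warning rather than failing.

## Cell-fraction comparison

The deconvolution itself (e.g. CIBERSORTx with the LM22 matrix) is
external; the package consumes its output table, tolerating that
dialect's extra columns. Samples with deconvolution quality p ≥ 0.05
are dropped; each cell type is compared between risk groups by Wilcoxon
rank-sum (exact when both groups are ≤ 25 and tie-free, otherwise the
normal approximation with continuity correction) with Benjamini–
Hochberg control across types; an abundance summary lists types whose
mean fraction exceeds a floor (default 0.05) in every group.

## Synthetic cohorts

The generator produces the data structure the pipeline assumes, with
known truth:

* **Expression**: per-gene log-normal, location ~ N(2, 0.5²) and scale
  ~ U(0.4, 1.0) on the natural-log scale — FPKM-like right-skewed
  values of magnitude ~1–50 — with a 5% point mass of exact zeros.
* **True pairs**: `n_true_pairs` disjoint gene pairs whose two genes
  share location and scale, so the order indicator is near-balanced;
  otherwise the pair would be removed as near-constant and could never
  be recovered.
* **Survival**: inverse-transform sampling from an exponential or
  Weibull baseline (default Weibull, shape 1.2, rate 0.0117 ⇒ ~30-month
  median at η = 0) with hazard ∝ exp(η), η = Σ β_k s_k. Default effects
  (1.2, −1.2, 1.2): deliberately a *positive control* — strong enough
  that the stringent 1e-4 univariate screen retains every true pair at
  n = 300, so a recovery failure indicates a pipeline defect, not
  sampling noise. (Univariate screening attenuates each pair's marginal
  effect because the other pairs act as omitted covariates; moderate
  effects near 0.6–0.8 sit on the screen's power boundary at this n.)
* **Censoring**: independent U(0, c_max), with c_max calibrated by
  bisection so the expected censoring fraction hits the target (30%).
* **Platform distortion**: per-sample affine (ax + b, a > 0, b ≥ 0) or
  power (x^p, p > 0) maps, both strictly increasing on non-negative
  data and preserving the zero tie mass; user-supplied maps are
  spot-checked for monotonicity and rejected otherwise.
* **Mutation flags** (BRAF/NRAS-like): Bernoulli, optionally associated
  with η through a logistic link.
* **Cell fractions**: Dirichlet compositions with optional per-type
  concentration and group-wise log-offsets.

One `numpy` Generator seeded by the config drives every draw, so any
stage is replayable bit-for-bit.

What the generator does *not* emulate: gene–gene correlation beyond the
planted pairs, batch effects that are not within-sample monotone,
informative censoring, covariate-dependent hazards, or the LM22
deconvolution error structure. Tests passing on these cohorts therefore
validate the machinery (scoring, screening, selection, cutoffs,
inference) under the model's own assumptions — they do not certify
performance on real melanoma data, where effect sizes are weaker and
assumptions only approximate.

## Numerical choices and degenerate inputs

* Expression ties score 0 everywhere; an NA expression cell is a hard
  error (no imputation).
* MAD is unscaled; a constant gene (MAD 0) is always filtered.
* The screen's Newton iterations clip steps at ±2 and coefficients at
  ±15; |coef| at the cap is treated as monotone likelihood (see above).
* Pair-identity filter boundary: exactly 90% identical is retained
  (the rule is strictly "more than").
* ROC: horizon before the first event, beyond follow-up, or with
  S(t) ∈ {0, 1} is an error; Youden ties break toward the smaller
  threshold.
* Log-rank with any empty group, Cox with collinear or constant
  covariates, and comparisons with an empty group are errors with
  diagnostics; a feature constant across samples reports p = 1 with a
  warning instead.

## Problem sizes in the bundled analyses and tests

The analyses run a 300-patient × 100-gene cohort (4,950 pairs), chosen
so the full funnel — including 100-cycle consensus selection — and the
20-seed recovery experiment complete in minutes on one core while
leaving every stage nondegenerate (hundreds of events, thousands of
screened pairs, double-digit candidates). The type-I-error experiment
uses 2,000 permuted pair replicates at n = 200; the Cox recovery check
uses n = 2,000 with a single planted pair (no attenuation), recovering
the generating log-HR within ±0.1.

## Known limitations

* The bundled 33-pair melanoma signature is consumed as a fixture; the
  package does not attempt to re-derive it from public cohorts, and its
  printed cutoff (−1.130) depends on the original authors' exact ROC
  estimator settings, which are not recoverable.
* Only the KM cumulative/dynamic ROC estimator is provided (no
  nearest-neighbour smoothing, no confidence bands).
* No proportional-hazards diagnostics (e.g. Schoenfeld residuals).
* The lasso stage inherits coordinate-descent path discretisation from
  scikit-survival; penalties between grid points are snapped to the
  nearest fitted value.
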