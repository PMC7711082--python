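# Methods

This note documents the models and procedures implemented in
`fusionsig`, the choices made where the design was genuinely open, and
what the synthetic-data experiments do and do not demonstrate.

## Signature derivation

For each gene the model is a binomial GLM with logit link,

    logit P(fusion-positive) = b0 + b1 * expression + b2 * age + b3 * gleason,

fit by maximum likelihood (statsmodels `Logit`). Significance is the
two-sided Wald test of `b1`; the test-suite cross-checks both the
coefficient and the p-value against an independently written Newton
solver of the binomial log-likelihood to 1e-6.

Choices that were open and how they were resolved:

- **Gleason encoding** — numeric 6–9 rather than categorical dummies.
  Gleason is an ordinal severity scale, and a single slope costs fewer
  degrees of freedom in small cohorts.
- **Ranking criterion** — genes are ranked by the Wald p-value of the
  expression coefficient; ties break by ascending gene id so selection
  is deterministic.
- **Weight magnitude** — only the range [−1, 1] and the sign semantics
  are fixed by the signature contract; the magnitude is set to
  `(-log10 p) / max(-log10 p)` over the selected set. This is monotone
  in significance, hits the bounds exactly, and is self-normalizing
  (the top gene always carries |w| = 1). p-values of exactly 0 are
  clamped to the smallest positive double before the log.
- **Perfect separation / non-convergence** — such genes are flagged
  non-informative (coefficient 0, p-value 1) rather than refit with a
  penalized method. This keeps derivation deterministic and avoids
  silently mixing estimators; the count is logged. Constant-expression
  genes are flagged the same way without fitting.
- **No multiple-testing correction** — selection is by rank (top K),
  not by a p-value threshold, so adjustment would not change the
  selected set.
- **Missing covariates** — samples missing age or Gleason are dropped
  for all fits, with a logged count. Samples labeled `erg_other`
  (ERG fused to a non-TMPRSS2 partner) count as fusion-negative in the
  response, matching their TMPRSS2-ERG annotation.

## Single-sample scoring

The score is a weighted two-distribution running-sum statistic (the
BASE family of rank-based single-sample enrichment scores). For one
sample, genes are sorted by descending expression with exact ties broken
by ascending gene id. With magnitudes `v_i` in ranked order (|weight|
for signature genes, 0 otherwise):

    F(k) = sum_{i<=k} v_i / sum_i v_i          (foreground share)
    B(k) = sum_{i<=k} (1-v_i) / sum_i (1-v_i)  (background share)
    pre-score = F(k*) - B(k*),  k* = argmax_k |F(k) - B(k)|

with the smallest `k` taken on ties. The pre-score lies in [−1, 1]; it
is +1 only when all weighted mass precedes all background mass.

**Normalization.** The pre-score is divided by the mean |pre-score|
over M seeded uniform permutations of the magnitude vector across the
gene universe (default M = 1000). Division by a positive scale never
changes the sign and maps 0 to 0, unlike a z-score; the normalized value
reads as "times the deviation expected for a random gene set with the
same weight profile". A z-score variant was deliberately not used
because re-centering can flip signs of weak scores.

**Up/down combination.** The final score is the normalized up-set score
minus the normalized down-set score, both computed with one shared
permutation stream per sample (`default_rng([seed, sample_index])`, one
`permutation(N)` call per draw). Consequences, each covered by an exact
test: scores are invariant to any strictly increasing transform of a
sample's expression; negating every signature weight negates every
score bit-for-bit; scoring is deterministic given (matrix, signature,
M, seed).

**Numerical layout.** All running sums are strict left-to-right
accumulations (`cumsum`), and totals are taken as the final cumulative
entry, so the vectorized implementation is bit-identical to a literal
loop over cut positions — the oracle-equivalence tests assert exact
equality, not approximate.

Genes present in the matrix but absent from the signature participate
as background; signature genes missing from the matrix are dropped with
a warning (error if none remain). The statistic variant is recorded in
the score metadata, since other members of the BASE family differ in
normalization details.

## Evaluation

- **Wilcoxon rank-sum** — exact null distribution (integer subset-sum
  dynamic program over ranks) when combined n ≤ 12 and the pooled values
  have no ties; otherwise the normal approximation with tie correction
  and no continuity correction (so identical groups give p = 1 rather
  than an artifact of the half-unit shift). Two-sided p is
  `min(1, 2*min(P(U<=u), P(U>=u)))`.
- **ROC/AUC** — AUC by the Mann-Whitney identity on average ranks
  (tied pairs count 1/2), curve by threshold sweep; the trapezoidal area
  of the curve equals the pair-count AUC exactly.
- **Median split** — scores ≤ threshold go to the low group. The tie
  side had to be fixed somewhere; low keeps the high group strictly
  above the threshold. The quantile is configurable (default 0.5).
- **Log-rank / Kaplan-Meier** — lifelines' standard
  observed-minus-expected statistic with hypergeometric variances and
  product-limit curves. If either group has no events the result is
  flagged degenerate; if there are no events at all, chi-square 0 and
  p = 1 are reported with the flag.
- **Spearman** — ranked Pearson with average ranks, t-approximation
  p-value; zero-variance inputs are rejected as undefined.
- **Strata** — the default report covers all samples, fusion-positive,
  fusion-negative and Gleason-7; arbitrary column==value filters can be
  configured. Empty strata are recorded as skipped with the reason.
  The survival block also reports whether the high-score group has the
  higher event rate: the direction of the prognostic association is a
  property of the data (it reverses between fusion-positive and
  fusion-negative subgroups in real cohorts), so it is an output, not an
  assumption. No follow-up horizon is applied; p-values are unadjusted.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: two fusion
groups; signal genes shifted up or down in fusion-positive samples;
age and Gleason covariates; right-censored survival whose hazard depends
on pathway activity.

    x_gs = mu_g + d_g * delta * a_s + eps_gs,  mu_g ~ N(0,1), eps ~ N(0, noise_sd^2)

with latent activity `a_s = 1` for fusion-positive (and `erg_other`)
samples, 0 for negatives, plus optional jitter. Survival is exponential
with `hazard = baseline_hazard * exp(hazard_coef * a_s)` and independent
exponential censoring; `censor_rate = 0` yields complete follow-up.

Defaults describe a mid-sized annotated cohort: 2000 genes, 300 samples,
half fusion-positive, 200 signal genes split evenly up/down, a 1.5-SD
shift against unit noise, age 66 ± 7 years, Gleason mass (0.25, 0.5,
0.15, 0.1) over 6–9 (7 is the most common grade at diagnosis), baseline
hazard 0.05 and censoring rate 0.02 per abstract time unit (≈ 70–90% of
events observed over typical draws). Gene baselines have unit spread so
rankings are non-trivial; time units carry no calendar semantics.

Deliberate simplifications: signal-gene placement is deterministic
(first `n_signal_genes` ids) because gene labels are arbitrary — this
also lets cohorts drawn with different seeds share one ground truth,
which is how held-out validation cohorts are constructed. Gleason is
generated independently of fusion status (it enters the derivation as a
covariate, not a mediator). The generator does not model read counts,
platform/batch effects, gene-gene correlation, or fusion breakpoints.
Passing tests therefore demonstrate correctness of the statistical
machinery and recoverability under the stated generating model — not
performance on real tumor data, where correlated expression and weaker,
heterogeneous effects will reduce recovery and AUC.

## Problem sizes used in validation

The acceptance experiments use a 2000-gene / 300-sample cohort for
derivation recovery (top-200 selection against 200 planted genes, with
a held-out cohort for AUC), 50 replicates of 400 samples for
median-split log-rank power at `hazard_coef = 1`, and 200 replicates of
80 samples for null calibration (effect and hazard link both zero).
Permutation counts of 30–200 are used there; the scoring default of
1000 gives a smoother normalizer but does not change any conclusion, as
the normalizer's Monte-Carlo error enters all samples symmetrically.

## Known limitations

- The exact formulation of the original BASE statistic differs across
  descriptions; this package fixes one concrete, fully specified variant
  and records its name in score metadata rather than claiming fidelity
  to any particular prior implementation.
- Per-gene logistic fits ignore gene-gene correlation; the signature is
  a marginal construction, as in the underlying approach.
- The exponential survival model has constant hazards; real cohorts
  with non-proportional hazards may behave differently under the median
  split.
- Expression must be complete (no NA); imputation is out of scope
  because rank statistics on imputed values are not meaningful without
  an error model.
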