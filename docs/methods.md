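# Methods

## Statistical model

The pipeline treats per-sample natural-log metabolite abundances as
multivariate Gaussian. Under that model, the conditional independence
structure is encoded in the precision matrix `Omega` (the inverse
covariance): metabolites *i* and *j* are conditionally independent given
everything else exactly when `Omega_ij = 0`, and the strength of a direct
relationship is the full-conditional partial correlation

    rho_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj).

`uratenet` estimates this by inverting the *correlation* matrix of the
joint variable block — all metabolites plus the conditioning covariates
(age, sex, and additive SNP dosages for the pooled network). Using the
correlation rather than the covariance matrix changes nothing in the
partial correlations (they are scale-free) but improves conditioning and
makes intermediate quantities unit-free. Covariate rows of the inverse are
used only to absorb covariate-driven covariance; they are never reported.

Edge significance uses the exact-under-Gaussianity Student-*t* statistic
`t = r sqrt(df/(1-r^2))` with `df = n - 2 - k`, where `k = (p - 2) + q` is
the number of conditioned variables per pair (all other metabolites plus
`q` covariates). With `k` in the hundreds the df correction is material; a
flag (`adjust_df=False`) switches to the naive `n - 2` convention for
comparison. Multiple testing over the `p(p-1)/2` pairs is controlled with
Benjamini–Hochberg step-up FDR at q = 0.05 (Benjamini–Yekutieli available
via `fdr_method="by"` for worst-case dependence). The decision object
records the realized data-driven cutoff — the largest p-value called
significant — since that number is a useful plausibility check against any
particular dataset's analysis.

The reported network is the induced subgraph on all metabolites within
shortest-path distance 3 of the focal metabolite (urate). "Induced"
matters: edges between two metabolites at equal distance from the focus are
kept, which is how tightly wired clusters (steroid conjugates, dipeptides)
appear complete even when only one member touches urate directly.

### Sex-stratified comparison

Partial correlations are re-estimated separately within males and females,
conditioning on age and all other metabolites but *not* on the SNP block
(the halved samples make the enlarged joint set unreliable) and not on sex
itself (constant within a stratum, hence singular). Each pair is compared
with the Fisher z-test for partial correlations,

    z = (atanh r_1 - atanh r_2) / sqrt(1/(n_1-k-3) + 1/(n_2-k-3)),

two-sided against the standard normal. The `k` adjustment in the standard
error is exposed as a flag for the same reason as above. Two Bonferroni
families are supported: the edges of the pooled network (`alpha/#edges`,
e.g. 0.05/58 = 8.6e-4 for a 58-edge network) and all pairs
(`alpha/(p(p-1)/2)`, e.g. 0.05/62,128 = 8.0e-7 at p = 353).

### Covariate effect models

Each network metabolite's log abundance is regressed by OLS on sex
(0 = male, 1 = female) and urate-lowering medication (0/1), adjusted for
age. The default is one joint model per metabolite
(`abundance ~ sex + medication + age`); a `separate` form fits the two
predictors in independent age-adjusted models, since either reading of the
usual reporting layout is defensible — on orthogonal designs the two agree
exactly, which the tests verify. Significance uses a Bonferroni family of
(#network metabolites × 2) tests (e.g. 76 tests → 6.6e-4 at 38 metabolites).

## Preprocessing chain

Fixed order: run-day median normalization → missingness filter → natural
log → imputation → duplicate removal.

* **Normalization** divides each observed raw ion count by the median of
  observed values of the same metabolite within the same measurement day,
  exactly cancelling multiplicative per-day instrument drift. Granularity
  is per metabolite per day; a global per-day median would mix metabolite
  scales.
* **Filtering** drops metabolites with missing fraction strictly above
  20 % first, then samples strictly above 10 % on the reduced matrix. The
  order matters (a sample can be rescued by removal of a doomed
  metabolite) and the comparisons are strict: exactly 20 % missing is
  kept.
* **Imputation** is seeded single-imputation chained equations: missing
  cells start at the metabolite's observed mean, then each metabolite with
  missing cells is repeatedly (10 iterations, fixed column order)
  regressed on a screened predictor set and its missing cells replaced by
  prediction plus residual-scaled Gaussian noise. Two choices deserve
  explanation:
  * *Stochastic by default.* Deterministic conditional-mean imputation
    leaves imputed cells with zero residual variance; downstream, that
    measurably inflates the GGM's false-discovery proportion (in our
    experiments roughly threefold at 10 % missingness). The noise term
    restores the residual variance the estimator assumes, and a fixed seed
    keeps runs byte-reproducible. Deterministic mode is retained as an
    option.
  * *Predictor screening.* Imputation models use at most the 10 most
    correlated metabolites with absolute correlation ≥ 0.1 (recomputed each
    iteration), not all p-1 columns. Besides being standard
    chained-equations practice for wide matrices, this keeps imputed cells
    from becoming linear blends of *every* other metabolite — blends that
    the full-conditional estimator would otherwise partially "discover" as
    spurious edges. Measured at n = 1,764, p = 40, 10 % missing: FDP ≈ 0.22
    with all-predictor imputation vs ≈ 0.07 with screening, at unchanged
    TPR ≈ 1.0.
* **Duplicate removal** drops listed duplicate-analyte columns (the
  alternate-measurement situation) after imputation, so the network is
  estimated once on the deduplicated matrix.

Imputation draws on metabolites only (not covariates), so planted covariate
effects are slightly attenuated in imputed cells: recovered sex/medication
betas at 10 % missingness sit ~5–15 % below their planted values. This is
an honest property of the chain, visible in the acceptance report.

## Synthetic cohorts

The generator emulates the statistical anatomy of a population metabolomics
cohort for which the original data cannot be shipped:

* **Planted truth.** Each unordered metabolite pair receives an edge
  independently with probability `edge_density`; edge partial correlations
  are uniform in magnitude on `[0.2, 0.4]` with random sign. Off-diagonal
  precision entries are set accordingly (unit diagonal), positive
  definiteness is enforced by bounded additive diagonal inflation
  (smallest-eigenvalue margin 0.05), and the matrix is then standardized by
  a diagonal congruence so the implied covariance has exactly unit
  variances — both operations leave the edge support intact, and the final
  partial correlations are re-read from the finished matrix, so planted and
  realized values agree exactly. Unit variances pin covariate effect sizes
  to a per-SD scale.
* **Cohort draw.** Latent log abundances are multivariate normal with the
  planted covariance, shifted per sample by additive covariate effects
  (age in years, sex 0/1, medication 0/1, SNP dosages 0/1/2), given
  per-metabolite baselines, exponentiated to an ion-count scale, and
  multiplied by per-(day, metabolite) batch factors `exp(N(0, 0.1^2))`
  across 20 contiguous measurement days. A duplicate analyte is appended
  as its source column plus independent Gaussian noise calibrated so the
  Pearson correlation with the source is 0.60, mirroring the known
  duplicated xanthine measurement. Missing cells are injected completely
  at random (default 10 %) or by per-analyte left-censoring
  (below-detection-limit mode), which stress-tests the imputation model's
  MCAR assumption.
* **Covariate marginals** default to the cohort the analysis emulates:
  age ≈ N(60.9, 11²) clipped to 32–81 years, 51.5 % female, urate-lowering
  medication in 1.9 % of women and 7.7 % of men, three SNPs at MAF 0.3.
  All are configurable. The missingness rate and its per-metabolite
  distribution are *guesses* — the source cohort's per-class rates are not
  public — and uniform MCAR at 10 % is deliberately harsher than real
  Metabolon-style data, where missingness concentrates in metabolites that
  the 20 % filter removes: under uniform MCAR the >10 %-per-sample rule
  removes a substantial minority of samples (row missingness is
  ~Binomial(p, 0.1)), which real cohorts do not show.
* **Scale.** Default simulations use p = 40 metabolites (plus the
  duplicate) at n = 1,764 samples with edge density 0.075 (~58 expected
  edges, matching the size of the motivating network). The estimator
  itself handles the full ~350-metabolite scale — inversion of a ~360²
  matrix is trivial — but the packaged study conditions keep simulation
  batteries fast enough to replicate twenty-fold routinely.

What passing tests on these cohorts shows: the estimator chain recovers a
known sparse conditional-independence structure through the full
preprocessing stack at realistic scale, with FDR behaving as advertised.
What it does not show: robustness to non-Gaussian abundance distributions,
informative (non-MCAR) missingness beyond the censoring stress mode,
heteroscedastic batch effects, or the adversarial correlation structure of
real lipid panels.

## Numerical choices and degenerate inputs

* Singular joint correlation matrices fail loudly with a suggestion to
  pass `ridge > 0` (which adds `ridge·I` before inversion); silent
  regularization would invisibly change reported coefficients. Constant
  columns are named in the error.
* `|r| = 1` yields the smallest positive float as p-value, with a warning.
* The inverted matrix is symmetrized and its diagonal pinned to 1;
  symmetry holds to 1e-12 by test.
* Tie-breaks are deterministic everywhere: fixed imputation column order,
  lexicographic edge ordering in tables, sorted JSON keys. Two runs with
  the same configuration and seed produce byte-identical artifacts; for
  this reason the run manifest carries no wall-clock timestamps.
* A chained regression with a rank-deficient design falls back to mean
  imputation for that metabolite with a logged warning; metabolites with
  fewer than two observed values are rejected outright.

## Known limitations

* Full-conditional partial correlations require `n > p + q + 2`; there is
  deliberately no sparse/regularized (graphical-lasso) fallback, since the
  method under study is the sample partial correlation.
* Single imputation understates imputation uncertainty in the edge
  p-values; at the default 10 % missingness the measured excess FDP is a
  few points (see above), and covariate betas attenuate slightly. Multiple
  imputation with pooling would remove this at the cost of a multi-matrix
  interface.
* SNP selection is out of scope: the conditioning SNP set is an input
  (simulated dosages by default), not discovered by any association scan.
* No graph drawing; exports (GraphML, TSV edge lists) target external
  viewers.
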