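# Methods

This note documents the statistical models implemented in `twinwell`, the
assumptions they make, the synthetic-data design used to exercise them, and
the numerical choices that matter for reproducing results.

## Study design being modelled

A population twin register observes parent-rated child wellbeing (Cantril
ladder, 0–10) at a pre-pandemic baseline and at roughly six-monthly survey
waves through and after a pandemic.  Waves are collapsed into four periods
— `pre` (baseline, wave 0), `early` (waves 1–2), `late` (waves 3–4),
`post` (waves 5–6) — to gain power; the collapsing map is configurable
(`datatypes.DEFAULT_PERIOD_MAP`).  Participation is partial: not every
child is observed in every period, and fathers respond far less often than
mothers.  Two cross-sectional comparison cohorts (a representative panel
and a clinical sample) contribute to the mean-trend analysis only.

## Twin likelihood machinery (`twin_core`, `fiml`)

All genetic models are Gaussian structural models for family-level
observation vectors, estimated by raw-data (full-information) maximum
likelihood: each family contributes the multivariate-normal log-density of
its *observed* subvector, obtained by selecting the corresponding
submatrix of the expected covariance.  This equals the complete-data
likelihood when nothing is missing and is unbiased under missingness that
is ignorable given the model (the generator's missingness is MCAR).

Implementation notes:

* Families are bucketed once by (zygosity, missingness pattern); repeated
  evaluations batch the Cholesky factors of all same-size submatrices and
  compute quadratic forms from a single flattened design product.  This
  keeps cohorts with hundreds of patterns cheap to iterate.
* Indefinite expected covariances do not return `-inf` (a hard barrier
  stalls quasi-Newton line searches); they return a large finite penalty
  that grows with the negative-eigenvalue mass, sloping back toward the
  feasible region.
* Optimization is L-BFGS-B with five jittered restarts by default
  (gradient tolerance 1e-8); the best converged solution is kept and
  non-convergence is flagged on the returned fit rather than raised.
* Variance components are parameterized through unconstrained
  matrix-square-root / path-coefficient parameters internally and reported
  as variances, so they are non-negative by construction without active
  bounds.  Estimates can therefore sit exactly on the zero boundary, as
  variance components often do.
* Confidence intervals are profile-likelihood based: the set of values at
  which −2lnL rises by at most χ²₁(0.95) = 3.841, found by bracketing and
  bisection, with the lower limit truncated at zero for variances.
  Standard errors, where reported, come from an in-house
  central-difference Hessian.
* The ACE-vs-ADE family choice uses the classical twin-correlation rule:
  ACE when r_MZ < 2·r_DZ, ADE when r_MZ > 2·r_DZ.  The tie resolves to
  ACE because C and D are not jointly identifiable from twin pairs.
  Twin correlations are Pearson correlations with pairs double-entered,
  since twin order within a pair is arbitrary.

## Correlated-factors model (`correlated_factors`)

Four-period multivariate ACE decomposition: symmetric PSD matrices Σ_A,
Σ_C, Σ_E over periods, each parameterized by its Cholesky factor (10 free
entries per matrix), plus a mean model with per-period intercepts and
linear age and sex effects shared across zygosity (30 covariance + 6 mean
parameters).  Expected family covariance: within-twin block
Σ_A + Σ_C + Σ_E; cross-twin block k·Σ_A + Σ_C, k = 1 (MZ) / 0.5 (DZ).

Data preparation follows the single-rater convention: the maternal rating
is used when both parents rated a child, the paternal rating otherwise;
"other" raters are excluded; multiple ratings of a child within a
collapsed period resolve to the earliest wave.  Periods in which no
complete twin pair is observed for either zygosity are flagged — the A/C
split is unidentified there.

Starting values come from method-of-moments component matrices
(2(S_MZ−S_DZ), 2S_DZ−S_MZ, W−S_MZ from pairwise-complete double-entered
covariances), projected to the PSD cone.

Derived quantities: component correlations
r_X[i,j] = Σ_X[i,j]/√(Σ_X[i,i]·Σ_X[j,j]); standardized variance
(diagonal) and covariance (off-diagonal) shares Σ_X[i,j]/Σ_P[i,j], which
sum to one per cell across A, C, E.  Standardization uses the
model-implied phenotypic matrix (the component sum), not a separately
fitted saturated variance — this keeps shares internally consistent when
independently rounded published entries disagree in the second decimal
(e.g. a printed phenotypic variance of 1.06 against a component sum of
1.07; correlations reconstructed from such rounded inputs can shift by
±0.01).

## Psychometric multi-rater model (`multirater`)

Per period, the four observed variables (m1, f1, m2, f2) decompose into a
common latent child phenotype with ACE structure — the part both parents
agree on, with loadings fixed at 1 — plus rater-specific A/C/E per
parent.  The rater-specific C components are rater *bias*: a deviation a
parent applies identically to both twins (consistent over- or
under-rating).  Rater-specific A is a genuine, heritable behavior seen
by one parent only; rater-specific E is idiosyncratic error.  Implied
covariances:

* var(m_j) = (A+C+E) + (A_m+C_m+E_m), likewise for fathers;
* cov(m_j, f_j) = A + C + E (the common variance; contains no genetic
  sharing term, so it is equal for MZ and DZ by construction);
* cov(m_1, m_2) = k·A + C + k·A_m + C_m;
* cov(m_i, f_j), i≠j = k·A + C.

Nine variance components plus four mean parameters (mother and father
intercepts, age, sex) are estimated per period; periods are fitted
independently.  Rater-specific parts are simulated independently across
periods; this is irrelevant for the period-wise fits but means the
generator does not emulate persistence of a parent's bias over time.

The companion *constrained saturated* model estimates per-zygosity 4×4
covariances under (a) parental-agreement covariance equal across zygosity
and twin order, (b) cross-twin cross-rater covariance equal across twin
order, and (c) variances equal across twin order; it is tested against
the free per-zygosity matrices by a 9-df likelihood-ratio test at
α = 0.05.  Data simulated from the psychometric model satisfy the
constraints, so the test doubles as an optimizer health check.

**View decomposition.**  Two summaries are emitted.  Per rater, the
common share (A+C+E)/var(rating) and the six ACE shares of that rater's
total variance, of which the specific-C share is the rater-bias index.
Pooled, the common-view share counts the common phenotype once:

common / (common + mother-specific + father-specific).

The pooled definition is primary: with near-equal rater variances the
per-rater common share is forced to equal the cross-rater correlation,
whereas the published headline trajectory for this design (common view
≈ 35% → 21% → 25% against cross-rater correlations 0.50 → 0.35 → 0.40)
is reproduced exactly by the pooled definition (0.50/1.50 = 33%,
0.35/1.65 = 21%, 0.40/1.60 = 25%).  Note the two constraints this
implies: given a cross-rater correlation r and equal rater variances, the
pooled common share is r/(2−r), so a share of exactly 35% cannot coexist
with r = 0.50 — the reference calibration reproduces r = 0.50 exactly
and a pooled share of 33.3%.

A practical corollary, asserted in the tests: fitting a *single-rater*
ACE model to mother ratings generated with nonzero C_m recovers
C ≈ C_common + C_m — rater bias inflates shared-environment estimates,
which is the reason the multi-rater model exists.

## Mean-trend mixed models (`mean_trends`)

`Y = (β1 + u) + β2·wave + β3·sex + β4·age + β5·PEA + β6·rater + e`, with
wave categorical (reference = earliest wave by default, configurable to
match designs whose first observed wave is wave 2), female vs male, low
and middle parental educational attainment vs high, father vs mother.
Random intercepts: none (OLS limit), per individual, or individual nested
within family; the marginal family covariance is
σ²_f·J + σ²_i·blockdiag(J) + σ²_e·I.  Estimation is ML (not REML): β is
profiled out by GLS at each variance evaluation and the 1–3 log-variance
parameters are optimized by Nelder-Mead; families are bucketed by their
observation-count signature so the per-signature covariance inverse is
computed once per evaluation.  The implementation is cross-checked in the
test suite against statsmodels `MixedLM` (ML) to 1e-4 on fixed effects
and log-likelihood.

t statistics use the residual degrees of freedom N − p; exact
mixed-model df rules vary between implementations, so reported df are
informative rather than an inferential contract.  With one observation
per individual (cross-sectional cohorts) the individual and residual
variances are identified only through their sum; the fit carries a flag
and the fixed effects are unaffected.

Estimated marginal means per wave evaluate the fitted model at the
sample-average design row with the wave indicators switched — covariates
at observed proportions, age at its mean — making EMM differences equal
the wave coefficients and invariant to reference recoding.

Baseline selection for longitudinal children follows the latest
pre-pandemic record (by `year` when available, else by wave), ties
resolving deterministically to the first record in input order.

## Synthetic-data generator (`synthetic_data`, `scenarios`)

The generator emulates the twin-register design: MZ/DZ pairs (A sharing
1 / 0.5, C shared, E unshared), a latent phenotype drawn from the
correlated-factors matrices, optional dual parental ratings adding
rater-specific components per period, linear covariate effects, and MCAR
missingness.  Defaults:

* Reference component matrices: the four-period A/C/E estimates of the
  wellbeing study (`scenarios.SIGMA_A/C/E`; all PSD, smallest eigenvalues
  0.10–0.16), total baseline variance ≈ 1.07.
* Mean model: per-period intercepts (8.2, 7.6, 7.5, 7.9), age slope
  −0.02/yr, female +0.05, father-rating offset −0.05 — the Cantril means
  and covariate effects of the register cohort.
* Ages uniform 7–12 at baseline (register inclusion ages), advanced by
  the survey calendar; sexes 50/50 (MZ pairs same-sex); parental
  education low/middle/high at 11/37/52%.
* Missingness: baseline available for 83% of families (drawn per family,
  so co-twins share the baseline flag); each pandemic period observed
  with probability √0.4 ≈ 0.63 per child, making the pairwise overlap
  between any two periods ≈ 40%, the register's reported overlap;
  mothers respond for ~95% of observed families, fathers for ~45–60%.
* Multi-rater calibrations per period: common ACE solved from the
  published cross-rater and cross-twin cross-rater correlations, with
  rater-specific shares matching the published view decompositions
  (e.g. pre-pandemic: common C = 0.37, E = 0.13, A ≈ 0; mother-specific
  A/C/E = 0.14/0.27/0.09 of unit variance).
* Mixed-model cohorts: a twin-longitudinal design (10,442 families ≈
  20,884 children) with the register's published fixed effects and
  variance components family 0.35 / individual 0.30 / residual 0.40
  (total ≈ the observed phenotypic variance, twin ICC ≈ 0.6), and a
  cross-sectional clinical-scale design (2,557 singletons over six
  waves, ages 8–18, 13% father raters).

Scores are continuous by default — every model treats the ladder as
continuous, and continuous scores keep estimator tests exact.  The 0–10
rounding/clipping (`discretize_cantril`) is opt-in; away from the clip
boundaries it adds ≈ 1/12 of rounding variance.

What the generator does *not* emulate — so what passing tests do not
show: informative (non-MCAR) participation, "other" raters,
recruitment/stratification and panel weighting, ordinal measurement
effects when discretization interacts with the scale ends, persistence
of rater bias across periods, and age heterogeneity within a period
beyond the survey calendar.  Recovery results on these cohorts therefore
demonstrate correctness of the estimators under the stated model, not
robustness to violations of it.

## Problem sizes and runtime

The bundled experiments are sized so the full suite and the acceptance
script each run in minutes on one core: correlated-factors recovery uses
2,500 pairs per zygosity (fully observed), multi-rater recovery 3,000
pairs per zygosity, and the mixed models the full cohort scales above.
Property suites specified over hundreds of replicates run scaled down
(8–40 replicates, smaller cohorts) with unchanged tolerances.  Monte-Carlo
standard errors at these scales: ≈ 0.025 for the recovered C variances,
≈ 0.005 for the cross-rater correlation, ≈ 1 percentage point for view
shares, ≈ 0.011 for the mixed-model sex effect (so a ±0.02 recovery check
on that coefficient retains a small per-seed failure probability by
design).

## Known limitations

* No ordinal/threshold liability models; the ladder is treated as
  Gaussian.
* No dominance (ADE) variant of the longitudinal or multi-rater fits —
  the choice rule selects ACE for every published correlation pair in
  this design — though the univariate machinery supports D.
* When a profile interval fails to bracket, the univariate machinery
  falls back to a seeded nonparametric pair bootstrap (200 resamples)
  with a warning; the multivariate fits report profile CIs only.
* The constrained-saturated and psychometric fits assume both-rater
  families exist; with none, cross-rater cells are flagged unidentified.
* Mixed-model t degrees of freedom are approximate (N − p).
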