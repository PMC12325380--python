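# twinwell

Genetically informed analysis of child wellbeing across a large societal
disruption, built for the design used by Dutch cohort studies of the
COVID-19 pandemic: parent-rated wellbeing on the 0–10 Cantril ladder,
observed at a pre-pandemic baseline and across pandemic and post-pandemic
survey waves, in monozygotic (MZ) and dizygotic (DZ) twin pairs rated by
one or both parents.

It is aimed at behavior-geneticists and epidemiologists who want to run —
or stress-test on synthetic data — three linked analyses:

1. **Longitudinal correlated-factors ACE model.** Phenotypic variance at
   each of four periods (pre, early, late, post) is decomposed into
   additive genetic (A), shared environmental (C) and non-shared
   environmental (E) parts, with each component correlating freely across
   periods.  The expected twin-pair covariance is

   Σ_within = Σ_A + Σ_C + Σ_E,  Σ_cross = k·Σ_A + Σ_C,

   with genetic sharing k = 1 (MZ) or ½ (DZ).  Derived outputs are the
   genetic/environmental correlations r_X[i,j] =
   Σ_X[i,j]/√(Σ_X[i,i]Σ_X[j,j]) and standardized variance/covariance
   shares Σ_X[i,j]/Σ_P[i,j].

2. **Psychometric multi-rater model.** Each parent's rating splits into a
   common latent child phenotype (rater agreement) plus rater-specific
   A/C/E; the rater-specific shared-environment components C_m, C_f are
   rater bias (a deviation one parent applies to both twins).  A
   constrained saturated model (parental-agreement covariance equal across
   zygosity; cross-twin cross-rater covariance equal across twin order)
   is fitted alongside, with a likelihood-ratio check.

3. **Mean-trend mixed models.** A random-intercept LMM
   `Y = (β1 + u) + β2·wave + β3·sex + β4·age + β5·PEA + β6·rater + e`
   with individual intercepts optionally nested within family, fitted by
   maximum likelihood, plus estimated marginal means per wave.

All fitting uses raw-data (full-information) maximum likelihood, so
families contribute through whatever subset of ratings they have — the
partial wave overlap typical of these cohorts needs no listwise deletion.
Because the original register data are not public, the package ships a
seeded synthetic-cohort generator with known A/C/E structure (including
dual raters, covariates, and MCAR missingness) so that every stage is
testable end to end; `twinwell.scenarios` bundles reference parameter sets
at published magnitudes.

## Worked example

```python
import numpy as np
from twinwell import scenarios
from twinwell.datatypes import SimulationConfig
from twinwell.synthetic_data import simulate_twin_cohort
from twinwell.correlated_factors import fit_correlated_factors, derive
from twinwell.twin_core import twin_correlations, choose_ace_or_ade

cfg = SimulationConfig(n_mz_pairs=1000, n_dz_pairs=1000, seed=7,
                       cf_params=scenarios.reference_cf_params())
df = simulate_twin_cohort(cfg)          # long table, one row per rating

tc = twin_correlations(df, rater="mother", period="pre")
print(f"r_MZ = {tc.r_mz:.2f}, r_DZ = {tc.r_dz:.2f}  ->  {choose_ace_or_ade(tc)} model")

params, fit = fit_correlated_factors(df, n_restarts=2, seed=7)
print("C diagonal:", np.round(np.diag(params.sigma_c), 2))
der = derive(params)
print(f"rA(pre, early) = {der.r_a[0,1]:.2f}")
print(f"standardized C share (pre) = {der.shares['c'][0,0]:.2f}")
```

prints

```
r_MZ = 0.85, r_DZ = 0.67  ->  ACE model
C diagonal: [0.56 0.9  0.76 0.54]
rA(pre, early) = 0.49
standardized C share (pre) = 0.52
```

The MZ correlation is below twice the DZ correlation, so the ACE family is
selected.  The fitted shared-environment variances (0.56, 0.90, 0.76,
0.54) recover the generating values (0.52, 0.86, 0.80, 0.50) within
sampling error at 1,000 pairs per zygosity: the C variance surges during
the lockdown periods and returns to baseline afterwards.  The genetic
correlation between baseline and the first lockdown year is well below 1,
and shared environment accounts for about half of baseline variance.

## Command line

```bash
twinwell run-all --seed 42 --out results_demo      # simulate + all fits
twinwell simulate --seed 1 --out cohort_out        # cohort CSV only
```

Outputs are plain CSV tables (twin correlations, unstandardized and
standardized ACE estimates, per-period cross-rater correlations and
common/specific view shares, LMM coefficients and marginal means) plus a
run log with seeds, likelihoods and convergence flags.  Reruns with the
same config and seed are byte-identical.

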