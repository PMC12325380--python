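"""Reference parameter sets for the child-wellbeing pandemic analysis.

These are the study conditions the package ships with: the fitted four-period
A/C/E component matrices of parent-rated wellbeing in a Dutch population twin
cohort, period-wise psychometric multi-rater decompositions, and the mixed
model fixed effects for the population twin cohort (NTR-scale, longitudinal)
and a clinical cohort (DREAMS-scale, cross-sectional).  They drive the demo
pipeline, the simulation-recovery tests and the acceptance script.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    PERIODS,
    AceParams,
    CFParams,
    LmmSpec,
    MeanModel,
    MissingnessConfig,
    MultiRaterParams,
)

# ---------------------------------------------------------------------------
# Four-period correlated-factors components (wellbeing variance scale).
# Periods: pre-pandemic baseline, early pandemic (first lockdown year),
# late pandemic (second lockdown year), post-pandemic.
# ---------------------------------------------------------------------------

SIGMA_A = np.array(
    [
        [0.38, 0.21, 0.08, 0.07],
        [0.21, 0.39, 0.15, 0.10],
        [0.08, 0.15, 0.34, 0.11],
        [0.07, 0.10, 0.11, 0.38],
    ]
)

SIGMA_C = np.array(
    [
        [0.52, 0.21, 0.33, 0.35],
        [0.21, 0.86, 0.28, 0.36],
        [0.33, 0.28, 0.80, 0.40],
        [0.35, 0.36, 0.40, 0.50],
    ]
)

SIGMA_E = np.array(
    [
        [0.17, 0.02, 0.00, 0.07],
        [0.02, 0.15, 0.04, 0.04],
        [0.00, 0.04, 0.18, 0.06],
        [0.07, 0.04, 0.06, 0.23],
    ]
)

#: Published phenotypic variance/covariance block (rounded independently of
#: the component matrices, hence e.g. 1.06 vs the component sum 1.07).
PHENOTYPIC_PRINTED = np.array(
    [
        [1.06, 0.45, 0.41, 0.49],
        [0.45, 1.40, 0.47, 0.49],
        [0.41, 0.47, 1.32, 0.57],
        [0.49, 0.49, 0.57, 1.10],
    ]
)


def reference_cf_params() -> CFParams:
    """Correlated-factors generating parameters at the reference estimates."""
    return CFParams(
        sigma_a=SIGMA_A.copy(),
        sigma_c=SIGMA_C.copy(),
        sigma_e=SIGMA_E.copy(),
        intercepts=np.array([8.2, 7.6, 7.5, 7.9]),
        beta_age=-0.02,
        beta_sex=0.05,
    )


# ---------------------------------------------------------------------------
# Psychometric multi-rater decompositions per period (rater variance = 1).
# Common ACE solved from the period's cross-rater and cross-twin cross-rater
# correlations; rater-specific shares from the reported view decompositions.
# ---------------------------------------------------------------------------

MULTIRATER_BY_PERIOD: dict[str, MultiRaterParams] = {
    "pre": MultiRaterParams(
        common=AceParams(a2=0.00, c2=0.37, e2=0.13),
        mother_specific=AceParams(a2=0.14, c2=0.27, e2=0.09),
        father_specific=AceParams(a2=0.08, c2=0.33, e2=0.09),
    ),
    "early": MultiRaterParams(
        common=AceParams(a2=0.16, c2=0.17, e2=0.02),
        mother_specific=AceParams(a2=0.08, c2=0.47, e2=0.10),
        father_specific=AceParams(a2=0.08, c2=0.39, e2=0.18),
    ),
    "late": MultiRaterParams(
        common=AceParams(a2=0.08, c2=0.25, e2=0.07),
        mother_specific=AceParams(a2=0.10, c2=0.40, e2=0.10),
        father_specific=AceParams(a2=0.08, c2=0.39, e2=0.13),
    ),
    "post": MultiRaterParams(
        common=AceParams(a2=0.02, c2=0.27, e2=0.14),
        mother_specific=AceParams(a2=0.39, c2=0.16, e2=0.02),
        father_specific=AceParams(a2=0.15, c2=0.36, e2=0.06),
    ),
}


# ---------------------------------------------------------------------------
# Mixed-model fixed effects (wellbeing points on the 0-10 ladder).
# ---------------------------------------------------------------------------


def ntr_lmm_spec() -> LmmSpec:
    """Population twin cohort: longitudinal, baseline wave 0 reference.

    Variance components are not part of the published coefficient table;
    family 0.35 / individual 0.30 / residual 0.40 gives a total close to the
    pre-pandemic phenotypic variance of ~1.06 with a twin intraclass
    correlation around 0.6, in line with the twin correlations.
    """
    return LmmSpec(
        intercept=8.2,
        wave_effects={1: -0.593, 2: 0.007, 3: -0.722, 4: -0.434, 5: -0.286, 6: -0.339},
        beta_female=0.047,
        beta_age=-0.021,
        beta_pea_low=-0.168,
        beta_pea_middle=-0.112,
        beta_father=-0.046,
        var_family=0.35,
        var_individual=0.30,
        var_residual=0.40,
    )


def dreams_lmm_spec() -> LmmSpec:
    """Clinical cohort: cross-sectional waves 2-7, wave 2 reference."""
    return LmmSpec(
        intercept=7.0,
        wave_effects={3: -0.421, 4: -0.085, 5: 0.059, 6: 0.205, 7: 0.215},
        beta_female=-0.344,
        beta_age=-0.143,
        beta_pea_low=0.280,
        beta_pea_middle=0.039,
        beta_father=0.200,
        var_family=0.0,
        var_individual=0.45,
        var_residual=0.65,
    )


def reference_missingness() -> MissingnessConfig:
    """Partial wave overlap: baseline available for ~83% of families, each
    pandemic period observed for ~63% of children (so that any two pandemic
    periods share roughly 40% of the sample), fathers responding for roughly
    half the observed families and mothers nearly always."""
    return MissingnessConfig(
        period_obs_prob={"pre": 0.83, "early": 0.63, "late": 0.63, "post": 0.63},
        rater_prob={
            "mother": {p: 0.95 for p in PERIODS},
            "father": {"pre": 0.60, "early": 0.45, "late": 0.45, "post": 0.45},
        },
    )


def reference_mean_model() -> MeanModel:
    return MeanModel(
        intercepts={"pre": 8.2, "early": 7.6, "late": 7.5, "post": 7.9},
        beta_age=-0.02,
        beta_sex=0.05,
        father_offset=-0.05,
    )
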