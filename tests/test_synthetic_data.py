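"""Generator correctness: known-structure cohorts, missingness, discretization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from twinwell import scenarios
from twinwell.correlated_factors import build_cf_expected_cov, prepare_cf_data
from twinwell.datatypes import (
    PERIODS,
    CFParams,
    MeanModel,
    MissingnessConfig,
    SimulationConfig,
)
from twinwell.synthetic_data import (
    LmmCohortDesign,
    apply_missingness,
    discretize_cantril,
    simulate_lmm_cohort,
    simulate_twin_cohort,
)


def _flat_means() -> MeanModel:
    return MeanModel(intercepts={p: 0.0 for p in PERIODS}, beta_age=0.0, beta_sex=0.0,
                     father_offset=0.0)


def test_mz_twins_identical_when_only_genetic_variance():
    """With C = E = 0 and A = I, MZ co-twins share every deviate."""
    cfg = SimulationConfig(
        n_mz_pairs=200, n_dz_pairs=1, seed=1,
        cf_params=CFParams(np.eye(4), np.zeros((4, 4)), np.zeros((4, 4))),
        mean_model=_flat_means(),
    )
    df = simulate_twin_cohort(cfg)
    wide = df[df.zygosity == "MZ"].pivot_table(
        index="family_id", columns=["period", "individual_id"], values="wellbeing",
        aggfunc="first",
    )
    for period in PERIODS:
        block = wide[period].to_numpy()
        np.testing.assert_allclose(block[:, 0], block[:, 1], atol=1e-12)


def test_cross_twin_covariance_vanishes_without_familial_variance():
    """A = C = 0 leaves only E, so co-twins are uncorrelated."""
    cfg = SimulationConfig(
        n_mz_pairs=4000, n_dz_pairs=4000, seed=2,
        cf_params=CFParams(np.zeros((4, 4)), np.zeros((4, 4)), np.eye(4)),
        mean_model=_flat_means(),
    )
    df = simulate_twin_cohort(cfg)
    d = prepare_cf_data(df)
    for g in (0, 1):
        sub = d.y[d.group == g]
        cov = np.cov(sub, rowvar=False)
        assert np.abs(cov[:4, 4:]).max() < 0.06  # ~3 MC standard errors


def test_cross_twin_covariance_matches_closed_form():
    """Baseline components a2=0.38, c2=0.52, e2=0.17 give MZ cross-twin
    covariance a2+c2=0.90 and DZ 0.5*a2+c2=0.71 (Monte-Carlo vs closed form)."""
    a2, c2, e2 = 0.38, 0.52, 0.17
    cfg = SimulationConfig(
        n_mz_pairs=50_000, n_dz_pairs=50_000, seed=3,
        cf_params=CFParams(a2 * np.eye(4), c2 * np.eye(4), e2 * np.eye(4)),
        mean_model=_flat_means(),
    )
    df = simulate_twin_cohort(cfg)
    d = prepare_cf_data(df)
    mc_se = np.sqrt(((a2 + c2 + e2) ** 2 + 0.9**2) / 50_000)
    for g, expected in ((0, a2 + c2), (1, 0.5 * a2 + c2)):
        sub = d.y[d.group == g]
        cross = np.cov(sub[:, 0], sub[:, 4])[0, 1]
        assert abs(cross - expected) < 3 * mc_se


@pytest.mark.parametrize(
    "latent, expected",
    [(8.4, 8.0), (-1.2, 0.0), (12.7, 10.0), (4.5, 4.0), (7.0, 7.0)],
)
def test_discretize_cantril_rounds_and_clips(latent, expected):
    assert discretize_cantril([latent])[0] == expected


@given(st.floats(-20, 20), st.floats(-20, 20))
def test_discretize_cantril_monotone(a, b):
    lo, hi = sorted([a, b])
    da, db = discretize_cantril([lo, hi])
    assert da <= db


def test_discretize_variance_adds_rounding_noise(rng):
    """Away from the clip boundaries, rounding adds ~1/12 uniform variance."""
    latent = rng.normal(5.0, 1.2, size=400_000)
    disc = discretize_cantril(latent)
    assert abs(np.var(disc) - (np.var(latent) + 1.0 / 12.0)) < 0.02


def test_missingness_identity_and_rater_removal(small_cf_cohort):
    full = MissingnessConfig()
    out = apply_missingness(small_cf_cohort, full, seed=1)
    pd.testing.assert_frame_equal(out, small_cf_cohort.reset_index(drop=True))

    cfg = SimulationConfig(
        n_mz_pairs=50, n_dz_pairs=50, seed=4,
        multirater_by_period=scenarios.MULTIRATER_BY_PERIOD,
    )
    df = simulate_twin_cohort(cfg)
    no_dad = MissingnessConfig(
        rater_prob={"mother": {p: 1.0 for p in PERIODS},
                    "father": {p: 0.0 for p in PERIODS}}
    )
    out = apply_missingness(df, no_dad, seed=1)
    assert not (out["rater"] == "father").any()
    assert (out["rater"] == "mother").sum() == (df["rater"] == "mother").sum()


def test_missingness_pairwise_overlap_matches_binomial_expectation():
    """Observation probability sqrt(0.4) per period gives ~40% of children
    observed in both of two given periods."""
    p = np.sqrt(0.4)
    cfg = SimulationConfig(
        n_mz_pairs=5000, n_dz_pairs=5000, seed=5,
        cf_params=scenarios.reference_cf_params(),
        missingness=MissingnessConfig(
            period_obs_prob={"pre": 1.0, "early": p, "late": p, "post": 1.0}
        ),
    )
    df = simulate_twin_cohort(cfg)
    seen = df.groupby("individual_id")["period"].agg(set)
    frac = np.mean([{"early", "late"} <= s for s in seen])
    assert abs(frac - 0.4) < 3 * np.sqrt(0.4 * 0.6 / 20_000)


def test_baseline_flag_shared_within_family():
    cfg = SimulationConfig(
        n_mz_pairs=400, n_dz_pairs=400, seed=6,
        cf_params=scenarios.reference_cf_params(),
        missingness=MissingnessConfig(period_obs_prob={"pre": 0.5}),
    )
    df = simulate_twin_cohort(cfg)
    pre = df[df.period == "pre"]
    by_fam = pre.groupby("family_id")["individual_id"].nunique()
    assert set(by_fam.unique()) == {2}  # never one twin without the other


def test_identical_seeds_give_byte_identical_tables(tmp_path):
    cfg = dict(
        n_mz_pairs=60, n_dz_pairs=60, seed=99,
        cf_params=scenarios.reference_cf_params(),
        multirater_by_period=scenarios.MULTIRATER_BY_PERIOD,
        missingness=scenarios.reference_missingness(),
    )
    a = simulate_twin_cohort(SimulationConfig(**cfg))
    b = simulate_twin_cohort(SimulationConfig(**cfg))
    assert a.to_csv(index=False) == b.to_csv(index=False)


def test_simulator_covariance_matches_builder_for_random_psd_params(rng):
    """Empirical covariance of simulated vectors tracks the model-implied
    expected covariance for randomly drawn PSD parameter sets."""
    for _ in range(3):
        mats = []
        for scale in (0.4, 0.5, 0.3):
            L = rng.normal(0, np.sqrt(scale / 4), (4, 4))
            mats.append(L @ L.T + 0.05 * np.eye(4))
        params = CFParams(*mats)
        cfg = SimulationConfig(
            n_mz_pairs=4000, n_dz_pairs=4000, seed=int(rng.integers(2**20)),
            cf_params=params, mean_model=_flat_means(),
        )
        d = prepare_cf_data(simulate_twin_cohort(cfg))
        for g, zyg in ((0, "MZ"), (1, "DZ")):
            emp = np.cov(d.y[d.group == g], rowvar=False)
            exp = build_cf_expected_cov(params, zyg)
            mc_se = np.sqrt((np.outer(np.diag(exp), np.diag(exp)) + exp**2) / 4000)
            assert np.all(np.abs(emp - exp) < 3.5 * mc_se)


def test_marginal_variance_is_sum_of_common_and_specific(multirater_cohort):
    mrp = scenarios.MULTIRATER_BY_PERIOD
    for period in ("pre", "early"):
        for rater in ("mother", "father"):
            sub = multirater_cohort[
                (multirater_cohort.period == period) & (multirater_cohort.rater == rater)
            ]
            expected = getattr(mrp[period], f"{rater}_total")
            assert abs(np.var(sub["wellbeing"]) - expected) < 0.08


def test_non_psd_component_matrix_rejected():
    bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
    with pytest.raises(ValueError, match="sigma_a"):
        CFParams(np.kron(np.eye(2), bad), np.zeros((4, 4)), np.eye(4))


# --- LMM cohort generator ---------------------------------------------------


def test_lmm_cohort_noise_free_equals_linear_predictor():
    spec = scenarios.ntr_lmm_spec()
    spec.var_family = spec.var_individual = spec.var_residual = 0.0
    df = simulate_lmm_cohort(
        spec, LmmCohortDesign(style="twin-longitudinal", n_families=50), seed=1
    )
    pred = (
        spec.intercept
        + df["wave"].map(lambda w: spec.wave_effects.get(w, 0.0))
        + spec.beta_female * (df.sex == "F")
        + spec.beta_age * df.age
        + df["pea"].map({"low": spec.beta_pea_low, "middle": spec.beta_pea_middle,
                         "high": 0.0})
        + spec.beta_father * (df.rater == "father")
    )
    np.testing.assert_allclose(df["wellbeing"], pred, atol=1e-9)


def test_lmm_cohort_family_intercept_drives_within_family_correlation():
    spec = scenarios.ntr_lmm_spec()
    spec.wave_effects = {}
    spec.beta_female = spec.beta_age = 0.0
    spec.beta_pea_low = spec.beta_pea_middle = spec.beta_father = 0.0
    spec.var_family, spec.var_individual, spec.var_residual = 1.0, 0.0, 0.0
    df = simulate_lmm_cohort(
        spec, LmmCohortDesign(style="twin-longitudinal", n_families=300, waves=(0,)),
        seed=2,
    )
    spread = df.groupby("family_id")["wellbeing"].agg(lambda s: s.max() - s.min())
    np.testing.assert_allclose(spread, 0.0, atol=1e-9)


def test_lmm_cohort_cross_sectional_one_row_per_child():
    df = simulate_lmm_cohort(
        scenarios.dreams_lmm_spec(),
        LmmCohortDesign(style="cross-sectional", n_families=500, waves=(2, 3, 4)),
        seed=3,
    )
    assert (df.groupby("individual_id").size() == 1).all()
    assert set(df["wave"]) <= {2, 3, 4}
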