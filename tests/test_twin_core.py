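"""Likelihood machinery: expected covariances, FIML, fits, CIs, LRT."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.stats import multivariate_normal

from twinwell.datatypes import AceParams, CFParams, FitResult, MeanModel, SimulationConfig, PERIODS
from twinwell.fiml import PatternedData, fiml_loglik
from twinwell.synthetic_data import simulate_twin_cohort
from twinwell.correlated_factors import prepare_cf_data
from twinwell.twin_core import (
    choose_ace_or_ade,
    expected_cov_univariate,
    fit_model,
    fit_univariate_ace,
    lrt,
    profile_ci,
    profile_ci_univariate,
    twin_correlations,
)
from twinwell.datatypes import TwinCorrelations


# --- expected covariance ----------------------------------------------------


@pytest.mark.parametrize(
    "params, zyg, diag, off",
    [
        (AceParams(0.38, 0.52, 0.17), "MZ", 1.07, 0.90),
        (AceParams(0.38, 0.52, 0.17), "DZ", 1.07, 0.71),
        (AceParams(1.0, 0.0, 1e-12), "DZ", 1.0, 0.5),
        (AceParams(0.4, 0.0, 0.3, d2=0.2), "DZ", 0.9, 0.25),
    ],
)
def test_expected_cov_univariate(params, zyg, diag, off):
    cov = expected_cov_univariate(params, zyg)
    assert cov == pytest.approx(np.array([[diag, off], [off, diag]]), abs=1e-9)


def test_ace_and_ade_are_mutually_exclusive():
    with pytest.raises(ValueError, match="alternative families"):
        expected_cov_univariate(AceParams(0.3, 0.3, 0.2, d2=0.1), "MZ")


@given(
    a2=st.floats(0, 1), c2=st.floats(0, 1), e2=st.floats(0.01, 1),
)
def test_mz_cross_covariance_dominates_dz(a2, c2, e2):
    p = AceParams(a2, c2, e2)
    mz = expected_cov_univariate(p, "MZ")
    dz = expected_cov_univariate(p, "DZ")
    assert mz[0, 1] >= dz[0, 1] - 1e-12
    assert np.allclose(mz, mz.T)


@pytest.mark.parametrize(
    "r_mz, r_dz, expected",
    [(0.83, 0.67, "ACE"), (0.6, 0.15, "ADE"), (0.5, 0.25, "ACE")],
)
def test_ace_ade_choice_rule(r_mz, r_dz, expected):
    tc = TwinCorrelations(r_mz=r_mz, r_dz=r_dz, n_mz=100, n_dz=100)
    assert choose_ace_or_ade(tc) == expected


def test_ace_ade_choice_undefined_correlations():
    tc = TwinCorrelations(r_mz=np.nan, r_dz=0.5, n_mz=2, n_dz=100)
    with pytest.raises(ValueError):
        choose_ace_or_ade(tc)


# --- FIML -------------------------------------------------------------------


def test_fiml_standard_normal_at_mode():
    y = np.array([[0.0]])
    ll = fiml_loglik(y, np.zeros((1, 1)), [np.eye(1)], np.array([0]))
    assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)


def test_fiml_complete_data_equals_dense_density(rng):
    k = 4
    L = rng.normal(size=(k, k))
    cov = L @ L.T + 0.5 * np.eye(k)
    mu = rng.normal(size=k)
    y = rng.multivariate_normal(mu, cov, size=40)
    ll = fiml_loglik(y, np.tile(mu, (40, 1)), [cov], np.zeros(40, int))
    dense = multivariate_normal(mean=mu, cov=cov).logpdf(y).sum()
    assert ll == pytest.approx(dense, rel=1e-10)


def test_fiml_missing_pattern_matches_marginal_density_oracle(rng):
    """A family observed on 2 of 4 variables contributes exactly the
    marginal normal density of the observed pair."""
    k = 4
    L = rng.normal(size=(k, k))
    cov = L @ L.T + 0.5 * np.eye(k)
    mu = rng.normal(size=k)
    for obs_idx in ([0, 2], [1, 3], [0, 1, 3]):
        y = np.full((1, k), np.nan)
        vals = rng.normal(size=len(obs_idx))
        y[0, obs_idx] = vals
        ll = fiml_loglik(y, mu[None, :], [cov], np.array([0]))
        oracle = multivariate_normal(
            mean=mu[obs_idx], cov=cov[np.ix_(obs_idx, obs_idx)]
        ).logpdf(vals)
        assert ll == pytest.approx(oracle, rel=1e-10)


def test_fiml_non_pd_submatrix_is_barrier():
    """An indefinite expected covariance yields a barrier value far below
    any attainable log-likelihood, steering the optimizer away."""
    y = np.array([[0.1, 0.2]])
    bad = np.array([[1.0, 2.0], [2.0, 1.0]])
    assert fiml_loglik(y, np.zeros((1, 2)), [bad], np.array([0])) < -1e9


# --- univariate fits --------------------------------------------------------


def _simulate_pairs(a2, c2, e2, n, seed):
    cfg = SimulationConfig(
        n_mz_pairs=n, n_dz_pairs=n, seed=seed,
        cf_params=CFParams(a2 * np.eye(4), c2 * np.eye(4), e2 * np.eye(4)),
        mean_model=MeanModel(intercepts={p: 0.0 for p in PERIODS}, beta_age=0.0,
                             beta_sex=0.0),
    )
    d = prepare_cf_data(simulate_twin_cohort(cfg))
    mz = d.y[d.group == 0][:, [0, 4]]
    dz = d.y[d.group == 1][:, [0, 4]]
    return mz, dz


def test_univariate_fit_recovers_standardized_components():
    mz, dz = _simulate_pairs(0.35, 0.49, 0.16, 5000, seed=11)
    fit = fit_univariate_ace(mz, dz, n_restarts=3, seed=1)
    total = fit.params["a2"] + fit.params["c2"] + fit.params["e2"]
    assert fit.converged
    assert fit.params["a2"] / total == pytest.approx(0.35, abs=0.03)
    assert fit.params["c2"] / total == pytest.approx(0.49, abs=0.03)
    assert fit.params["e2"] / total == pytest.approx(0.16, abs=0.03)


def test_univariate_fit_matches_falconer_closed_form():
    mz, dz = _simulate_pairs(0.4, 0.35, 0.25, 10_000, seed=12)
    fit = fit_univariate_ace(mz, dz, n_restarts=2, seed=1)
    r_mz = np.corrcoef(np.r_[mz[:, 0], mz[:, 1]], np.r_[mz[:, 1], mz[:, 0]])[0, 1]
    r_dz = np.corrcoef(np.r_[dz[:, 0], dz[:, 1]], np.r_[dz[:, 1], dz[:, 0]])[0, 1]
    var = np.var(np.r_[mz.ravel(), dz.ravel()])
    total = fit.params["a2"] + fit.params["c2"] + fit.params["e2"]
    assert fit.params["a2"] / total == pytest.approx(2 * (r_mz - r_dz), abs=0.02)
    assert fit.params["c2"] / total == pytest.approx(2 * r_dz - r_mz, abs=0.02)
    assert fit.params["e2"] / total == pytest.approx(1 - r_mz, abs=0.02)
    assert total == pytest.approx(var, rel=0.05)


def test_univariate_fit_rejects_degenerate_input():
    const = np.ones((50, 2))
    with pytest.raises(ValueError, match="degenerate"):
        fit_univariate_ace(const, const)


def test_parameter_recovery_over_random_generating_sets(rng):
    """Median absolute error of standardized components stays below 0.03
    across random PSD generating sets (scaled-down replicate count)."""
    errors = []
    for i in range(8):
        shares = rng.dirichlet([3, 3, 3])
        shares[2] = max(shares[2], 0.1)
        shares /= shares.sum()
        a2, c2, e2 = shares
        mz, dz = _simulate_pairs(a2, c2, e2, 2000, seed=100 + i)
        fit = fit_univariate_ace(mz, dz, n_restarts=2, seed=i)
        total = sum(fit.params[k] for k in ("a2", "c2", "e2"))
        errors.extend(
            [
                abs(fit.params["a2"] / total - a2),
                abs(fit.params["c2"] / total - c2),
                abs(fit.params["e2"] / total - e2),
            ]
        )
    assert np.median(errors) < 0.03


# --- profile CIs ------------------------------------------------------------


def test_profile_ci_quadratic_matches_wald():
    """For a Gaussian mean the profile interval is estimate +/- 1.96 SE."""
    n, sigma = 400, 1.3
    rng = np.random.default_rng(7)
    y = rng.normal(0.3, sigma, n)
    mle = y.mean()

    def neg2ll(mu):
        return np.sum((y - mu) ** 2) / sigma**2  # + const

    lo, hi = profile_ci(neg2ll, mle, neg2ll(mle), lower_limit=None)
    se = sigma / np.sqrt(n)
    assert lo == pytest.approx(mle - 1.96 * se, abs=0.002)
    assert hi == pytest.approx(mle + 1.96 * se, abs=0.002)


def test_profile_ci_variance_component_boundary():
    """When C is truly absent the lower confidence bound sits at zero."""
    mz, dz = _simulate_pairs(0.6, 1e-12, 0.4, 800, seed=13)
    fit = fit_univariate_ace(mz, dz, n_restarts=2, seed=1)
    lo, hi = profile_ci_univariate(mz, dz, fit, "c2")
    assert lo == 0.0
    assert hi > fit.params["c2"]
    assert lo <= fit.params["c2"] <= hi


def test_profile_ci_coverage_univariate_ace():
    """~95% of profile intervals for c2 cover the generating value
    (scaled-down simulation coverage check)."""
    hits = 0
    n_rep = 20
    for i in range(n_rep):
        mz, dz = _simulate_pairs(0.35, 0.49, 0.16, 400, seed=300 + i)
        fit = fit_univariate_ace(mz, dz, n_restarts=1, seed=i)
        lo, hi = profile_ci_univariate(mz, dz, fit, "c2")
        hits += lo - 1e-9 <= 0.49 <= hi + 1e-9
    assert hits / n_rep >= 0.8


# --- twin correlations ------------------------------------------------------


def test_twin_correlations_identical_and_independent(small_cf_cohort, rng):
    df = small_cf_cohort[small_cf_cohort.period == "pre"].copy()
    # identical scores within pair -> r = 1
    fam_score = df.groupby("family_id")["wellbeing"].transform("mean")
    ident = df.assign(wellbeing=fam_score)
    tc = twin_correlations(ident, rater="mother", period="pre")
    assert tc.r_mz == pytest.approx(1.0, abs=1e-9)
    # independent scores -> r ~ 0
    shuffled = df.assign(wellbeing=rng.permutation(df["wellbeing"].to_numpy()))
    tc = twin_correlations(shuffled, rater="mother", period="pre")
    assert abs(tc.r_mz) < 0.1 and abs(tc.r_dz) < 0.1


def test_twin_correlations_recover_generating_values():
    """Generating r_MZ=0.83, r_DZ=0.67 (mother-rated baseline) is recovered
    to +/-0.01 at 20,000 pairs per zygosity."""
    a2, c2, e2 = 0.32, 0.51, 0.17  # r_mz=0.83, r_dz=0.67
    cfg = SimulationConfig(
        n_mz_pairs=20_000, n_dz_pairs=20_000, seed=14,
        cf_params=CFParams(a2 * np.eye(4), c2 * np.eye(4), e2 * np.eye(4)),
    )
    df = simulate_twin_cohort(cfg)
    tc = twin_correlations(df, rater="mother", period="pre")
    assert tc.r_mz == pytest.approx(0.83, abs=0.01)
    assert tc.r_dz == pytest.approx(0.67, abs=0.01)
    assert tc.n_mz == 20_000 and tc.n_dz == 20_000


def test_twin_correlations_too_few_pairs(small_cf_cohort):
    tiny = small_cf_cohort[small_cf_cohort.family_id < 1]
    with pytest.raises(ValueError, match="2 complete pairs"):
        twin_correlations(tiny, rater="mother", period="pre")


# --- LRT --------------------------------------------------------------------


def _fr(m2ll, n_params):
    return FitResult(params={}, minus2ll=m2ll, converged=True, n_obs=100,
                     n_params=n_params)


def test_lrt_identical_models_zero_statistic():
    stat, df, p = lrt(_fr(1234.5, 5), _fr(1234.5, 4))
    assert stat == 0.0 and df == 1 and p == pytest.approx(1.0)


def test_lrt_negative_statistic_flags_optimizer_failure():
    with pytest.raises(RuntimeError, match="negative"):
        lrt(_fr(1000.0, 5), _fr(990.0, 4))


def test_lrt_type_one_error_calibrated_against_closed_form(rng):
    """Testing a truly-zero regression slope: the LRT statistic follows
    chi-square(1), so rejections at the 5% level occur ~5% of the time
    (closed-form Gaussian likelihoods as the oracle)."""
    n, n_rep = 60, 400
    rejections = 0
    for _ in range(n_rep):
        x = rng.normal(size=n)
        y = 1.0 + rng.normal(size=n)  # known variance 1, slope truly zero
        xc = x - x.mean()
        slope = (xc @ y) / (xc @ xc)
        m2_full = np.sum((y - y.mean() - slope * xc) ** 2)
        m2_nested = np.sum((y - y.mean()) ** 2)
        stat, df, p = lrt(_fr(m2_full, 2), _fr(m2_nested, 1))
        rejections += p < 0.05
    rate = rejections / n_rep
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep)


def test_lrt_power_against_gross_violation(rng):
    n = 500
    x = rng.normal(size=n)
    y = 1.0 + 0.8 * x + rng.normal(size=n)
    xc = x - x.mean()
    slope = (xc @ y) / (xc @ xc)
    m2_full = np.sum((y - y.mean() - slope * xc) ** 2)
    m2_nested = np.sum((y - y.mean()) ** 2)
    _, _, p = lrt(_fr(m2_full, 2), _fr(m2_nested, 1))
    assert p < 1e-10


# --- optimizer behavior -----------------------------------------------------


def test_fit_model_scale_invariant_quadratic():
    target = np.array([2.0, -1.0, 0.5])

    def obj(x):
        return float(np.sum((x - target) ** 2))

    res = fit_model(obj, np.zeros(3), n_restarts=3, seed=1)
    assert res.success
    np.testing.assert_allclose(res.x, target, atol=1e-5)


def test_released_constraint_never_decreases_loglik():
    """The free univariate fit attains at least the likelihood of the same
    model with C forced to zero."""
    mz, dz = _simulate_pairs(0.35, 0.49, 0.16, 600, seed=15)
    full = fit_univariate_ace(mz, dz, n_restarts=2, seed=1)

    data = PatternedData(
        np.vstack([mz, dz]),
        np.ones((len(mz) + len(dz), 2, 1)),
        np.r_[np.zeros(len(mz), int), np.ones(len(dz), int)],
    )

    def neg2ll_ae(theta):
        mu, pa, pe = theta
        a2, e2 = pa * pa, pe * pe
        t = a2 + e2
        covs = [np.array([[t, a2], [a2, t]]), np.array([[t, 0.5 * a2], [0.5 * a2, t]])]
        ll = data.loglik(covs, np.array([mu]))
        return np.inf if not np.isfinite(ll) else -2 * ll

    res = fit_model(neg2ll_ae, np.array([0.0, 0.6, 0.5]), n_restarts=2, seed=1)
    assert full.minus2ll <= res.fun + 1e-6
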