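"""Shared twin-model machinery.

Expected covariance construction, the ACE/ADE family choice rule, generic
maximum-likelihood optimization with restarts, likelihood-ratio tests,
profile-likelihood confidence intervals, twin correlations, and the
univariate ACE/ADE fit used both directly and as a building block.
"""

from __future__ import annotations

import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import AceParams, FitResult, TwinCorrelations
from .fiml import PatternedData

__all__ = [
    "expected_cov_univariate",
    "choose_ace_or_ade",
    "fiml_loglik",
    "fit_model",
    "numeric_hessian",
    "profile_ci",
    "twin_correlations",
    "lrt",
    "fit_univariate_ace",
]

#: Cross-twin sharing coefficients for additive and dominance genetic variance.
K_ADDITIVE = {"MZ": 1.0, "DZ": 0.5}
K_DOMINANCE = {"MZ": 1.0, "DZ": 0.25}



def expected_cov_univariate(params: AceParams, zygosity: str) -> np.ndarray:
    """2x2 expected covariance of a twin pair for a single trait.

    The diagonal carries the total variance; the cross-twin covariance is
    ``k_A*a2 + c2 + k_D*d2`` with genetic sharing k_A = 1 (MZ) or 0.5 (DZ)
    and dominance sharing k_D = 1 (MZ) or 0.25 (DZ).
    """
    if zygosity not in K_ADDITIVE:
        raise ValueError(f"unknown zygosity {zygosity!r}")
    if params.c2 > 0 and params.d2 > 0:
        raise ValueError("c2 and d2 cannot both be nonzero: ACE and ADE are alternative families")
    total = params.total
    cross = K_ADDITIVE[zygosity] * params.a2 + params.c2 + K_DOMINANCE[zygosity] * params.d2
    return np.array([[total, cross], [cross, total]])


def choose_ace_or_ade(tc: TwinCorrelations) -> str:
    """Model-family choice from twin correlations.

    ACE when r_MZ < 2 r_DZ (shared environment indicated), ADE when
    r_MZ > 2 r_DZ (dominance indicated).  The tie resolves to ACE since C
    and D are not jointly identifiable from twin pairs alone.
    """
    if not (np.isfinite(tc.r_mz) and np.isfinite(tc.r_dz)):
        raise ValueError("twin correlations are undefined; cannot choose a model family")
    return "ACE" if tc.r_mz <= 2.0 * tc.r_dz else "ADE"


def fiml_loglik(y, mu, covs, group) -> float:
    """Raw-data multivariate-normal log-likelihood (see :mod:`twinwell.fiml`)."""
    from . import fiml

    return fiml.fiml_loglik(y, mu, covs, group)


def fit_model(
    objective: Callable[[np.ndarray], float],
    x0: np.ndarray,
    *,
    bounds: Sequence[tuple[float | None, float | None]] | None = None,
    n_restarts: int = 5,
    jitter: float = 0.1,
    seed: int = 0,
    gtol: float = 1e-8,
    names: Sequence[str] | None = None,
) -> optimize.OptimizeResult:
    """Minimize ``objective`` (a -2lnL) with multiple jittered restarts.

    The first start is ``x0`` itself; subsequent starts add multiplicative
    and additive jitter.  The best converged solution is returned; if no
    start converges, the best point found is returned with
    ``success=False`` so callers can flag a partial result.
    """
    x0 = np.asarray(x0, dtype=float)
    rng = np.random.default_rng(seed)
    best = None
    any_success = False
    for i in range(max(1, n_restarts)):
        if i == 0:
            start = x0
        else:
            start = x0 * (1.0 + jitter * rng.standard_normal(x0.size))
            start = start + 0.5 * jitter * rng.standard_normal(x0.size)
            if bounds is not None:
                lo = np.array([-np.inf if b[0] is None else b[0] for b in bounds])
                hi = np.array([np.inf if b[1] is None else b[1] for b in bounds])
                start = np.clip(start, lo, hi)
        res = optimize.minimize(
            objective,
            start,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 2000, "gtol": gtol, "ftol": 1e-10},
        )
        if best is None or (res.fun < best.fun - 1e-9 and np.isfinite(res.fun)):
            best = res
        any_success = any_success or bool(res.success)
        # a converged, clearly best solution early on: stop restarting
        if i >= 1 and any_success and best.success and i >= 2:
            break
    best.success = bool(best.success or any_success)
    return best


def numeric_hessian(f: Callable[[np.ndarray], float], x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian, adequate for standard errors of smooth
    likelihoods away from variance boundaries."""
    x = np.asarray(x, dtype=float)
    n = x.size
    H = np.empty((n, n))
    steps = h * np.maximum(1.0, np.abs(x))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = steps[i]
        for j in range(i, n):
            ej = np.zeros(n)
            ej[j] = steps[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * steps[i] * steps[j])
    return H


def profile_ci(
    profile_fn: Callable[[float], float],
    mle: float,
    min2ll: float,
    *,
    level: float = 0.95,
    lower_limit: float = 0.0,
    step: float | None = None,
    max_expand: int = 40,
    tol: float = 1e-4,
) -> tuple[float, float]:
    """Likelihood-based confidence interval for one parameter.

    ``profile_fn(v)`` returns the minimized -2lnL with the parameter fixed
    at ``v``.  The interval is the set of values where -2lnL rises at most
    ``chi2_{1,level}`` above the minimum; the lower bound respects the
    boundary at ``lower_limit`` (variance components cannot go negative),
    so reported lower bounds may equal it.
    """
    crit = float(stats.chi2.ppf(level, df=1))
    target = min2ll + crit

    if step is None:
        step = max(0.05 * max(abs(mle), 0.1), 1e-3)

    def crossing(lo: float, hi: float, f_lo: float, f_hi: float) -> float:
        # bisection for profile(-2lnL) == target between lo (inside) and hi (outside)
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            fm = profile_fn(mid)
            if fm <= target:
                lo, f_lo = mid, fm
            else:
                hi, f_hi = mid, fm
            if abs(hi - lo) < tol * max(1.0, abs(mle)):
                break
        return 0.5 * (lo + hi)

    # upper bound
    v, fv = mle, min2ll
    hi = None
    for i in range(1, max_expand + 1):
        cand = mle + step * (2.0 ** (i - 1))
        fc = profile_fn(cand)
        if fc > target:
            hi = crossing(v, cand, fv, fc)
            break
        v, fv = cand, fc
    if hi is None:
        raise RuntimeError("profile failed to bracket the upper bound")

    # lower bound
    v, fv = mle, min2ll
    lo = None
    for i in range(1, max_expand + 1):
        cand = mle - step * (2.0 ** (i - 1))
        if lower_limit is not None and cand <= lower_limit:
            f_lim = profile_fn(lower_limit)
            if f_lim <= target:
                lo = lower_limit
            else:
                lo = crossing(v, lower_limit, fv, f_lim)
            break
        fc = profile_fn(cand)
        if fc > target:
            lo = crossing(v, cand, fv, fc)
            break
        v, fv = cand, fc
    if lo is None:
        lo = lower_limit if lower_limit is not None else mle - step * 2.0**max_expand
    return (float(lo), float(hi))


def _double_entry_corr(pairs: np.ndarray) -> tuple[float, int]:
    """Pearson correlation of twin-1 vs twin-2 scores with pairs entered in
    both orders (twin order is arbitrary)."""
    complete = pairs[np.isfinite(pairs).all(axis=1)]
    n = complete.shape[0]
    if n < 2:
        return (np.nan, n)
    a = np.concatenate([complete[:, 0], complete[:, 1]])
    b = np.concatenate([complete[:, 1], complete[:, 0]])
    if np.std(a) == 0 or np.std(b) == 0:
        return (np.nan, n)
    return (float(np.corrcoef(a, b)[0, 1]), n)


def twin_correlations(
    data: pd.DataFrame,
    rater: str = "mother",
    period: str | None = None,
) -> TwinCorrelations:
    """Twin correlations from the canonical long table.

    Rows are filtered to one rater (and optionally one period), one score
    per child is retained (earliest wave), and pairs are double-entered.
    Pair counts refer to complete pairs.
    """
    df = data[data["rater"] == rater]
    if period is not None:
        df = df[df["period"] == period]
    df = df.sort_values("wave").drop_duplicates(subset=["individual_id"], keep="first")
    out: dict[str, tuple[float, int]] = {}
    for zyg in ("MZ", "DZ"):
        sub = df[df["zygosity"] == zyg]
        pairs = _pairs_matrix(sub)
        out[zyg] = _double_entry_corr(pairs)
    if out["MZ"][1] < 2 or out["DZ"][1] < 2:
        raise ValueError("need at least 2 complete pairs per zygosity")
    return TwinCorrelations(
        r_mz=out["MZ"][0], r_dz=out["DZ"][0], n_mz=out["MZ"][1], n_dz=out["DZ"][1]
    )


def _pairs_matrix(sub: pd.DataFrame) -> np.ndarray:
    """(n_families, 2) score matrix, twins ordered by individual id."""
    wide = (
        sub.sort_values("individual_id")
        .groupby("family_id")["wellbeing"]
        .apply(lambda s: list(s)[:2])
    )
    mat = np.full((len(wide), 2), np.nan)
    for i, vals in enumerate(wide):
        mat[i, : len(vals)] = vals
    return mat


def lrt(full: FitResult, nested: FitResult, *, tol: float = 1e-6) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested (constrained) model against the full.

    Returns (statistic, df, p).  A materially negative statistic signals an
    optimizer failure in one of the fits and raises.
    """
    stat = nested.minus2ll - full.minus2ll
    df = full.n_params - nested.n_params
    if df <= 0:
        raise ValueError("nested model must have fewer free parameters than the full model")
    if stat < -tol * max(1.0, abs(full.minus2ll)):
        raise RuntimeError(
            f"negative LRT statistic ({stat:.4g}): the 'full' model fit is worse than the nested fit"
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df))
    return (float(stat), int(df), p)


# ---------------------------------------------------------------------------
# univariate ACE / ADE fit
# ---------------------------------------------------------------------------


def fit_univariate_ace(
    mz_pairs: np.ndarray,
    dz_pairs: np.ndarray,
    *,
    family: str = "ACE",
    n_restarts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Maximum-likelihood univariate twin fit from pair matrices.

    ``mz_pairs`` and ``dz_pairs`` are ``(n, 2)`` score matrices (NaN for a
    missing co-twin handled by FIML).  Components are parameterized through
    path coefficients (variance = coefficient squared) so they stay
    non-negative without optimizer boundary pathologies; estimates are
    reported as variances.
    """
    if family not in ("ACE", "ADE"):
        raise ValueError("family must be 'ACE' or 'ADE'")
    mz = np.asarray(mz_pairs, dtype=float)
    dz = np.asarray(dz_pairs, dtype=float)
    y = np.vstack([mz, dz])
    keep = np.isfinite(y).any(axis=1)
    y = y[keep]
    group = np.concatenate([np.zeros(mz.shape[0], int), np.ones(dz.shape[0], int)])[keep]
    allv = y[np.isfinite(y)]
    if allv.size < 4 or np.var(allv) <= 1e-12:
        raise ValueError("degenerate input: zero variance or too few observations")

    x = np.ones((y.shape[0], 2, 1))
    data = PatternedData(y, x, group)

    def covs(theta: np.ndarray) -> list[np.ndarray]:
        mu, pa, px, pe = theta
        a2, x2, e2 = pa * pa, px * px, pe * pe
        total = a2 + x2 + e2
        if family == "ACE":
            cross_mz = a2 + x2
            cross_dz = 0.5 * a2 + x2
        else:
            cross_mz = a2 + x2
            cross_dz = 0.5 * a2 + 0.25 * x2
        return [
            np.array([[total, cross_mz], [cross_mz, total]]),
            np.array([[total, cross_dz], [cross_dz, total]]),
        ]

    def neg2ll(theta: np.ndarray) -> float:
        ll = data.loglik(covs(theta), np.array([theta[0]]))
        return np.inf if not np.isfinite(ll) else -2.0 * ll

    # moment-based start: Falconer decomposition of double-entered correlations
    var0 = float(np.var(allv))
    mu0 = float(np.mean(allv))
    r_mz, _ = _double_entry_corr(mz)
    r_dz, _ = _double_entry_corr(dz)
    if not (np.isfinite(r_mz) and np.isfinite(r_dz)):
        r_mz, r_dz = 0.5, 0.3
    if family == "ACE":
        a0 = np.clip(2.0 * (r_mz - r_dz), 0.02, 0.95) * var0
        x0_ = np.clip(2.0 * r_dz - r_mz, 0.02, 0.95) * var0
    else:
        a0 = np.clip(4.0 * r_dz - r_mz, 0.02, 0.95) * var0
        x0_ = np.clip(2.0 * r_mz - 4.0 * r_dz, 0.02, 0.95) * var0
    e0 = np.clip(1.0 - r_mz, 0.05, 1.0) * var0
    start = np.array([mu0, np.sqrt(a0), np.sqrt(x0_), np.sqrt(e0)])

    res = fit_model(neg2ll, start, n_restarts=n_restarts, seed=seed)
    mu, pa, px, pe = res.x
    comp = "c2" if family == "ACE" else "d2"
    params = {"mean": float(mu), "a2": float(pa * pa), comp: float(px * px), "e2": float(pe * pe)}
    return FitResult(
        params=params,
        minus2ll=float(res.fun),
        converged=bool(res.success),
        n_obs=data.n_obs,
        n_params=4,
        message=str(res.message),
    )


def profile_ci_univariate(
    mz_pairs: np.ndarray,
    dz_pairs: np.ndarray,
    fit: FitResult,
    component: str,
    *,
    family: str = "ACE",
    level: float = 0.95,
) -> tuple[float, float]:
    """Profile-likelihood CI for one variance component of the univariate fit."""
    mz = np.asarray(mz_pairs, dtype=float)
    dz = np.asarray(dz_pairs, dtype=float)
    y = np.vstack([mz, dz])
    keep = np.isfinite(y).any(axis=1)
    y = y[keep]
    group = np.concatenate([np.zeros(mz.shape[0], int), np.ones(dz.shape[0], int)])[keep]
    x = np.ones((y.shape[0], 2, 1))
    data = PatternedData(y, x, group)
    comp_order = ["a2", "c2" if family == "ACE" else "d2", "e2"]
    if component not in comp_order:
        raise ValueError(f"unknown component {component!r}")
    idx = comp_order.index(component)

    def make_covs(fixed_v: float):
        def covs(theta3: np.ndarray) -> list[np.ndarray]:
            paths = [None, None, None]
            free = [theta3[1], theta3[2]]
            j = 0
            for i in range(3):
                if i == idx:
                    paths[i] = np.sqrt(max(fixed_v, 0.0))
                else:
                    paths[i] = free[j]
                    j += 1
            a2, x2, e2 = (p * p for p in paths)
            total = a2 + x2 + e2
            if family == "ACE":
                cross_mz, cross_dz = a2 + x2, 0.5 * a2 + x2
            else:
                cross_mz, cross_dz = a2 + x2, 0.5 * a2 + 0.25 * x2
            return [
                np.array([[total, cross_mz], [cross_mz, total]]),
                np.array([[total, cross_dz], [cross_dz, total]]),
            ]

        return covs

    mle_paths = {k: np.sqrt(fit.params[k]) for k in comp_order}
    free_keys = [k for k in comp_order if k != component]

    def profile_fn(v: float) -> float:
        covs = make_covs(v)

        def neg2ll(theta3: np.ndarray) -> float:
            ll = data.loglik(covs(theta3), np.array([theta3[0]]))
            return np.inf if not np.isfinite(ll) else -2.0 * ll

        start = np.array([fit.params["mean"], mle_paths[free_keys[0]], mle_paths[free_keys[1]]])
        res = fit_model(neg2ll, start, n_restarts=2, seed=1)
        return float(res.fun)

    try:
        return profile_ci(
            profile_fn,
            mle=fit.params[component],
            min2ll=fit.minus2ll,
            level=level,
            lower_limit=0.0,
        )
    except RuntimeError:
        warnings.warn(
            f"profile interval for {component!r} failed to bracket; "
            "falling back to a seeded nonparametric bootstrap",
            stacklevel=2,
        )
        return bootstrap_ci_univariate(
            mz_pairs, dz_pairs, component, family=family, level=level
        )


def bootstrap_ci_univariate(
    mz_pairs: np.ndarray,
    dz_pairs: np.ndarray,
    component: str,
    *,
    family: str = "ACE",
    level: float = 0.95,
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile interval from a seeded nonparametric pair bootstrap,
    resampling twin pairs within zygosity."""
    rng = np.random.default_rng(seed)
    mz = np.asarray(mz_pairs, dtype=float)
    dz = np.asarray(dz_pairs, dtype=float)
    draws = []
    for b in range(n_boot):
        bmz = mz[rng.integers(0, mz.shape[0], mz.shape[0])]
        bdz = dz[rng.integers(0, dz.shape[0], dz.shape[0])]
        bfit = fit_univariate_ace(bmz, bdz, family=family, n_restarts=1, seed=b)
        draws.append(bfit.params[component])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return (float(lo), float(hi))
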