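"""Four-period correlated-factors ACE model.

Each period has its own additive-genetic (A), shared-environment (C) and
non-shared-environment (E) factors, which correlate freely across periods;
the three 4x4 component matrices are jointly PSD by construction (internal
matrix-square-root parameterization) and sum to the phenotypic covariance.
Fitting is raw-data maximum likelihood over all missingness patterns using
single-rater scores (maternal ratings preferred) with per-period intercepts
and linear age and sex effects in the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from .datatypes import DEFAULT_PERIOD_MAP, PERIODS, CFParams, FitResult
from .fiml import PatternedData
from .twin_core import fit_model

__all__ = [
    "CFDerived",
    "build_cf_expected_cov",
    "prepare_cf_data",
    "fit_correlated_factors",
    "component_correlations",
    "standardize_components",
    "derive",
    "reproduce_tables",
]

_COMPONENTS = ("a", "c", "e")


def build_cf_expected_cov(params: CFParams, zygosity: str) -> np.ndarray:
    """8x8 expected covariance over (twin1 x periods, twin2 x periods).

    Within-twin block = A + C + E; cross-twin block = k*A + C with genetic
    sharing k = 1 (MZ) or 0.5 (DZ).
    """
    if zygosity not in ("MZ", "DZ"):
        raise ValueError(f"unknown zygosity {zygosity!r}")
    k = 1.0 if zygosity == "MZ" else 0.5
    within = params.phenotypic
    cross = k * params.sigma_a + params.sigma_c
    return np.block([[within, cross], [cross.T, within]])


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


@dataclass
class CFData:
    """Wide per-family arrays for the correlated-factors likelihood."""

    y: np.ndarray  # (n_fam, 2k)
    x: np.ndarray  # (n_fam, 2k, p)
    group: np.ndarray  # 0 = MZ, 1 = DZ
    family_ids: np.ndarray
    periods: tuple[str, ...]
    n_mean_params: int
    flags: list[str] = field(default_factory=list)


def prepare_cf_data(
    df: pd.DataFrame,
    *,
    periods: tuple[str, ...] = PERIODS,
    period_map: dict[int, str] | None = None,
    covariates: bool = True,
) -> CFData:
    """Collapse the long table to one score per child x period and pivot to
    family-wide vectors.

    Rater selection uses the maternal rating when both parents rated a
    child; 'other' raters are excluded.  Multiple ratings of a child within
    a collapsed period resolve to the earliest wave.
    """
    df = df[df["rater"].isin(["mother", "father"])].copy()
    if period_map is not None or "period" not in df.columns:
        pmap = period_map or DEFAULT_PERIOD_MAP
        df["period"] = df["wave"].map(pmap)
    df = df[df["period"].isin(periods)]
    df["_rater_rank"] = (df["rater"] == "father").astype(int)
    chosen = (
        df.sort_values(["_rater_rank", "wave"], kind="stable")
        .drop_duplicates(subset=["individual_id", "period"], keep="first")
    )

    info = (
        chosen.sort_values("individual_id")
        .groupby("individual_id")
        .agg(family_id=("family_id", "first"), zygosity=("zygosity", "first"),
             sex=("sex", "first"))
    )
    piv_y = chosen.pivot(index="individual_id", columns="period", values="wellbeing")
    piv_age = chosen.pivot(index="individual_id", columns="period", values="age")
    for p in periods:
        if p not in piv_y.columns:
            piv_y[p] = np.nan
            piv_age[p] = np.nan
    piv_y = piv_y.loc[info.index, list(periods)]
    piv_age = piv_age.loc[info.index, list(periods)]

    fams = info["family_id"].to_numpy()
    fam_ids, fam_codes = np.unique(fams, return_inverse=True)
    twin_slot = np.zeros(len(info), dtype=int)
    # slot 0/1 by individual id order within family
    order = np.lexsort((info.index.to_numpy(), fam_codes))
    seen: dict[int, int] = {}
    for idx in order:
        f = fam_codes[idx]
        twin_slot[idx] = seen.get(f, 0)
        seen[f] = seen.get(f, 0) + 1
    keep = twin_slot < 2

    k = len(periods)
    n_fam = fam_ids.size
    y = np.full((n_fam, 2 * k), np.nan)
    ages = np.zeros((n_fam, 2 * k))
    female = np.zeros((n_fam, 2 * k))
    ymat = piv_y.to_numpy()
    amat = np.nan_to_num(piv_age.to_numpy())
    fem = (info["sex"].to_numpy() == "F").astype(float)
    for idx in np.flatnonzero(keep):
        f, t = fam_codes[idx], twin_slot[idx]
        y[f, t * k : (t + 1) * k] = ymat[idx]
        ages[f, t * k : (t + 1) * k] = amat[idx]
        female[f, t * k : (t + 1) * k] = fem[idx]

    zyg_by_fam = pd.Series(info["zygosity"].to_numpy(), index=fams).groupby(level=0).first()
    group = (zyg_by_fam.loc[fam_ids].to_numpy() == "DZ").astype(int)

    p_mean = k + (2 if covariates else 0)
    x = np.zeros((n_fam, 2 * k, p_mean))
    for t in range(2):
        for j in range(k):
            cell = t * k + j
            x[:, cell, j] = 1.0
            if covariates:
                x[:, cell, k] = ages[:, cell]
                x[:, cell, k + 1] = female[:, cell]

    flags = []
    for g, zname in ((0, "MZ"), (1, "DZ")):
        sub = y[group == g]
        for j, p in enumerate(periods):
            complete = np.isfinite(sub[:, j]) & np.isfinite(sub[:, k + j])
            if complete.sum() == 0:
                flags.append(f"no complete {zname} pairs in period '{p}'")
    obs_any = np.isfinite(y).any(axis=1)
    return CFData(
        y=y[obs_any],
        x=x[obs_any],
        group=group[obs_any],
        family_ids=fam_ids[obs_any],
        periods=tuple(periods),
        n_mean_params=p_mean,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _tril_unpack(v: np.ndarray, k: int) -> np.ndarray:
    L = np.zeros((k, k))
    L[np.tril_indices(k)] = v
    return L


def _nancov(a: np.ndarray, b: np.ndarray) -> float:
    m = np.isfinite(a) & np.isfinite(b)
    if m.sum() < 3:
        return 0.0
    return float(np.cov(a[m], b[m])[0, 1])


def _moment_start(y: np.ndarray, group: np.ndarray, k: int) -> tuple[np.ndarray, ...]:
    """Method-of-moments component matrices for starting values."""
    yc = y - np.nanmean(np.vstack([y[:, :k], y[:, k:]]), axis=0)[np.tile(np.arange(k), 2)]
    covs = {}
    for g in (0, 1):
        sub = yc[group == g]
        t1, t2 = sub[:, :k], sub[:, k:]
        both = np.vstack([t1, t2])
        within = np.empty((k, k))
        cross = np.empty((k, k))
        for i in range(k):
            for j in range(k):
                within[i, j] = _nancov(both[:, i], both[:, j])
                cross[i, j] = 0.5 * (_nancov(t1[:, i], t2[:, j]) + _nancov(t2[:, i], t1[:, j]))
        covs[g] = (within, 0.5 * (cross + cross.T))
    w = 0.5 * (covs[0][0] + covs[1][0])
    a = 2.0 * (covs[0][1] - covs[1][1])
    c = 2.0 * covs[1][1] - covs[0][1]
    e = w - covs[0][1]
    return tuple(_psd_project(m, floor=0.02) for m in (a, c, e))


def _psd_project(mat: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    mat = 0.5 * (mat + mat.T)
    w, v = np.linalg.eigh(mat)
    return (v * np.clip(w, floor, None)) @ v.T


def fit_correlated_factors(
    df: pd.DataFrame,
    *,
    periods: tuple[str, ...] = PERIODS,
    period_map: dict[int, str] | None = None,
    covariates: bool = True,
    n_restarts: int = 5,
    seed: int = 0,
) -> tuple[CFParams, FitResult]:
    """FIML fit of the correlated-factors ACE model.

    Returns the fitted component matrices (with mean coefficients) and a
    :class:`FitResult` whose parameter dictionary holds every distinct
    matrix entry named ``a[pre,early]`` etc.
    """
    data = prepare_cf_data(df, periods=periods, period_map=period_map, covariates=covariates)
    k = len(periods)
    n_tri = k * (k + 1) // 2
    patterned = PatternedData(data.y, data.x, data.group)

    def covs_from(theta: np.ndarray) -> list[np.ndarray]:
        mats = []
        for c_i in range(3):
            L = _tril_unpack(theta[c_i * n_tri : (c_i + 1) * n_tri], k)
            mats.append(L @ L.T)
        a, c, e = mats
        within = a + c + e
        out = []
        for kk in (1.0, 0.5):
            cross = kk * a + c
            out.append(np.block([[within, cross], [cross.T, within]]))
        return out

    def neg2ll(theta: np.ndarray) -> float:
        beta = theta[3 * n_tri :]
        ll = patterned.loglik(covs_from(theta), beta)
        return np.inf if not np.isfinite(ll) else -2.0 * ll

    a0, c0, e0 = _moment_start(data.y, data.group, k)
    tril = np.tril_indices(k)
    start_cov = np.concatenate(
        [np.linalg.cholesky(m + 1e-6 * np.eye(k))[tril] for m in (a0, c0, e0)]
    )
    mean0 = np.nanmean(np.vstack([data.y[:, :k], data.y[:, k:]]), axis=0)
    start_mean = np.concatenate([mean0, [0.0, 0.0]]) if covariates else mean0
    start = np.concatenate([start_cov, start_mean])

    res = fit_model(neg2ll, start, n_restarts=n_restarts, seed=seed)

    mats = {}
    for c_i, name in enumerate(_COMPONENTS):
        L = _tril_unpack(res.x[c_i * n_tri : (c_i + 1) * n_tri], k)
        mats[name] = L @ L.T
    beta = res.x[3 * n_tri :]
    params = CFParams(
        sigma_a=mats["a"],
        sigma_c=mats["c"],
        sigma_e=mats["e"],
        intercepts=beta[:k],
        beta_age=float(beta[k]) if covariates else 0.0,
        beta_sex=float(beta[k + 1]) if covariates else 0.0,
        periods=tuple(periods),
    )
    named: dict[str, float] = {}
    for name, m in mats.items():
        for i in range(k):
            for j in range(i + 1):
                named[f"{name}[{periods[i]},{periods[j]}]"] = float(m[i, j])
    for j, p in enumerate(periods):
        named[f"mean[{p}]"] = float(beta[j])
    if covariates:
        named["beta_age"] = float(beta[k])
        named["beta_sex"] = float(beta[k + 1])
    fit = FitResult(
        params=named,
        minus2ll=float(res.fun),
        converged=bool(res.success),
        n_obs=patterned.n_obs,
        n_params=res.x.size,
        message=str(res.message),
        flags=list(data.flags),
    )
    return params, fit


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


@dataclass
class CFDerived:
    """Correlations and standardized shares implied by CFParams."""

    r_a: np.ndarray
    r_c: np.ndarray
    r_e: np.ndarray
    r_p: np.ndarray
    shares: dict[str, np.ndarray]
    periods: tuple[str, ...]
    flags: list[str] = field(default_factory=list)


def _corr(mat: np.ndarray, name: str, flags: list[str]) -> np.ndarray:
    d = np.diag(mat).copy()
    if (d <= 0).any():
        flags.append(f"zero diagonal in {name}; correlations undefined there")
        d = np.where(d <= 0, np.nan, d)
    return mat / np.sqrt(np.outer(d, d))


def component_correlations(params: CFParams) -> CFDerived:
    """Within-component cross-period correlations r_X[i,j] =
    Sigma_X[i,j] / sqrt(Sigma_X[i,i] Sigma_X[j,j]) and the phenotypic
    correlation from the component sum."""
    flags: list[str] = []
    r_a = _corr(params.sigma_a, "sigma_a", flags)
    r_c = _corr(params.sigma_c, "sigma_c", flags)
    r_e = _corr(params.sigma_e, "sigma_e", flags)
    r_p = _corr(params.phenotypic, "phenotypic", flags)
    return CFDerived(
        r_a=r_a, r_c=r_c, r_e=r_e, r_p=r_p, shares={}, periods=params.periods, flags=flags
    )


def standardize_components(params: CFParams) -> CFDerived:
    """Standardized variance (diagonal) and covariance (off-diagonal) shares.

    Each cell of a component matrix is divided by the corresponding cell of
    the model-implied phenotypic matrix (the component sum), so per cell the
    three shares add to one.
    """
    flags: list[str] = []
    phen = params.phenotypic
    if (np.diag(phen) <= 0).any():
        raise ValueError("phenotypic variances must be positive")
    denom = phen.copy()
    zero_off = (denom == 0) & ~np.eye(len(params.periods), dtype=bool)
    if zero_off.any():
        flags.append("zero phenotypic covariance cell; share undefined there")
        denom = np.where(zero_off, np.nan, denom)
    shares = {
        "a": params.sigma_a / denom,
        "c": params.sigma_c / denom,
        "e": params.sigma_e / denom,
    }
    return CFDerived(
        r_a=np.empty(0), r_c=np.empty(0), r_e=np.empty(0), r_p=np.empty(0),
        shares=shares, periods=params.periods, flags=flags,
    )


def derive(params: CFParams) -> CFDerived:
    """Full derived set: correlations plus standardized shares."""
    corr = component_correlations(params)
    std = standardize_components(params)
    corr.shares = std.shares
    corr.flags.extend(std.flags)
    return corr


def reproduce_tables(params: CFParams, *, round_to: int = 2) -> dict[str, pd.DataFrame]:
    """Tidy result tables.

    ``unstandardized``: every distinct variance/covariance entry per
    component (phenotypic included) with the implied cross-period
    correlation; ``standardized``: the variance/covariance shares per
    component.  Values rounded to ``round_to`` decimals on output only.
    """
    der = derive(params)
    k = len(params.periods)
    mats = {
        "phenotypic": (params.phenotypic, der.r_p),
        "additive_genetic": (params.sigma_a, der.r_a),
        "shared_environment": (params.sigma_c, der.r_c),
        "nonshared_environment": (params.sigma_e, der.r_e),
    }
    rows = []
    for comp, (m, r) in mats.items():
        for i in range(k):
            for j in range(i + 1):
                rows.append(
                    {
                        "component": comp,
                        "period_row": params.periods[i],
                        "period_col": params.periods[j],
                        "estimate": round(float(m[i, j]), round_to),
                        "correlation": (
                            round(float(r[i, j]), round_to) if i != j else np.nan
                        ),
                    }
                )
    unstd = pd.DataFrame(rows)
    rows = []
    for comp, key in (
        ("additive_genetic", "a"),
        ("shared_environment", "c"),
        ("nonshared_environment", "e"),
    ):
        m = der.shares[key]
        for i in range(k):
            for j in range(i + 1):
                rows.append(
                    {
                        "component": comp,
                        "period_row": params.periods[i],
                        "period_col": params.periods[j],
                        "share": round(float(m[i, j]), round_to),
                    }
                )
    return {"unstandardized": unstd, "standardized": pd.DataFrame(rows)}
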