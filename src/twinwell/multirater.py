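"""Psychometric multi-rater twin model, fitted per pandemic period.

Both parents rate both twins; the four observed variables per family are
ordered (mother-twin1, father-twin1, mother-twin2, father-twin2).  Each
rating decomposes into a common latent child phenotype (rater agreement,
with its own ACE structure) plus rater-specific A/C/E.  The rater-specific
shared-environment components C_m / C_f are applied identically to both
twins by one rater and are therefore the rater-bias terms; the specific E
components are idiosyncratic per twin x rater.

The module also fits the constrained saturated covariance model used for
model checking: per-zygosity 4x4 covariance matrices under the equality of
same-twin cross-rater covariances across zygosity (and twin order) and of
cross-twin cross-rater covariances across twin order, with a likelihood
ratio test against the unconstrained matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from .datatypes import AceParams, FitResult, MultiRaterParams
from .fiml import PatternedData
from .twin_core import fit_model, lrt

__all__ = [
    "VAR_ORDER",
    "build_multirater_expected_cov",
    "prepare_multirater_data",
    "fit_psychometric",
    "fit_constrained_saturated",
    "decompose_views",
    "ViewDecomposition",
    "ConstrainedSaturatedFit",
]

#: Observed-variable order within a family.
VAR_ORDER = ("m1", "f1", "m2", "f2")


def build_multirater_expected_cov(params: MultiRaterParams, zygosity: str) -> np.ndarray:
    """4x4 expected covariance over (m1, f1, m2, f2).

    var(m_j) = common + mother-specific totals; cov(m_j, f_j) = common total
    (identical for MZ and DZ by construction — the zygosity-equality
    constraint of the saturated model holds automatically);
    cov(m_1, m_2) = k*A + C + k*A_m + C_m; cov(m_i, f_j) (cross-twin
    cross-rater) = k*A + C; k = 1 (MZ) or 0.5 (DZ).
    """
    if zygosity not in ("MZ", "DZ"):
        raise ValueError(f"unknown zygosity {zygosity!r}")
    k = 1.0 if zygosity == "MZ" else 0.5
    com, mo, fa = params.common, params.mother_specific, params.father_specific
    ct = com.total
    var_m = ct + mo.total
    var_f = ct + fa.total
    cross_common = k * com.a2 + com.c2
    c_mm = cross_common + k * mo.a2 + mo.c2
    c_ff = cross_common + k * fa.a2 + fa.c2
    return np.array(
        [
            [var_m, ct, c_mm, cross_common],
            [ct, var_f, cross_common, c_ff],
            [c_mm, cross_common, var_m, ct],
            [cross_common, c_ff, ct, var_f],
        ]
    )


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


@dataclass
class MultiRaterData:
    y: np.ndarray  # (n_fam, 4) in VAR_ORDER
    x: np.ndarray  # (n_fam, 4, 4) mean design: [int_m, int_f, age, female]
    group: np.ndarray  # 0 = MZ, 1 = DZ
    family_ids: np.ndarray
    flags: list[str] = field(default_factory=list)


def prepare_multirater_data(df: pd.DataFrame, period: str) -> MultiRaterData:
    """One period's ratings pivoted to (m1, f1, m2, f2) per family."""
    sub = df[(df["period"] == period) & df["rater"].isin(["mother", "father"])].copy()
    if sub.empty:
        raise ValueError(f"no ratings for period {period!r}")
    sub = sub.sort_values("wave", kind="stable").drop_duplicates(
        subset=["individual_id", "rater"], keep="first"
    )
    info = (
        sub.sort_values("individual_id")
        .groupby("individual_id")
        .agg(family_id=("family_id", "first"), zygosity=("zygosity", "first"),
             sex=("sex", "first"), age=("age", "first"))
    )
    fams = info["family_id"].to_numpy()
    fam_ids, fam_codes = np.unique(fams, return_inverse=True)
    twin_slot = np.zeros(len(info), dtype=int)
    seen: dict[int, int] = {}
    for idx in np.lexsort((info.index.to_numpy(), fam_codes)):
        f = fam_codes[idx]
        twin_slot[idx] = seen.get(f, 0)
        seen[f] = seen.get(f, 0) + 1

    n_fam = fam_ids.size
    y = np.full((n_fam, 4), np.nan)
    age = np.zeros((n_fam, 2))
    female = np.zeros((n_fam, 2))
    score = sub.set_index(["individual_id", "rater"])["wellbeing"]
    for idx, (ind, row) in enumerate(info.iterrows()):
        if twin_slot[idx] > 1:
            continue
        f, t = fam_codes[idx], twin_slot[idx]
        for r_i, rater in enumerate(("mother", "father")):
            if (ind, rater) in score.index:
                y[f, 2 * t + r_i] = score.loc[(ind, rater)]
        age[f, t] = 0.0 if pd.isna(row["age"]) else row["age"]
        female[f, t] = 1.0 if row["sex"] == "F" else 0.0

    x = np.zeros((n_fam, 4, 4))
    for t in range(2):
        for r_i in range(2):
            cell = 2 * t + r_i
            x[:, cell, r_i] = 1.0
            x[:, cell, 2] = age[:, t]
            x[:, cell, 3] = female[:, t]

    zyg_by_fam = pd.Series(info["zygosity"].to_numpy(), index=fams).groupby(level=0).first()
    group = (zyg_by_fam.loc[fam_ids].to_numpy() == "DZ").astype(int)

    flags = []
    both = np.isfinite(y[:, 0]) & np.isfinite(y[:, 1])
    both |= np.isfinite(y[:, 2]) & np.isfinite(y[:, 3])
    if not both.any():
        flags.append("no families with both raters; cross-rater cells unidentified")
    obs_any = np.isfinite(y).any(axis=1)
    return MultiRaterData(
        y=y[obs_any], x=x[obs_any], group=group[obs_any],
        family_ids=fam_ids[obs_any], flags=flags,
    )


# ---------------------------------------------------------------------------
# moments (starting values)
# ---------------------------------------------------------------------------


def _nancov(a: np.ndarray, b: np.ndarray) -> float:
    m = np.isfinite(a) & np.isfinite(b)
    if m.sum() < 3:
        return np.nan
    return float(np.cov(a[m], b[m])[0, 1])


def _sample_moments(data: MultiRaterData) -> dict[int, np.ndarray]:
    out = {}
    for g in (0, 1):
        sub = data.y[data.group == g]
        S = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                S[i, j] = _nancov(sub[:, i], sub[:, j])
        out[g] = S
    return out


# ---------------------------------------------------------------------------
# psychometric fit
# ---------------------------------------------------------------------------


def fit_psychometric(
    df: pd.DataFrame,
    period: str,
    *,
    n_restarts: int = 5,
    seed: int = 0,
) -> tuple[MultiRaterParams, FitResult]:
    """FIML estimates of the nine psychometric variance components.

    The mean model has mother and father intercepts plus linear age and sex
    effects.  Components are parameterized through path coefficients, so
    they are non-negative by construction; boundary pile-ups (component
    below 1e-4) are reported in the fit flags.
    """
    data = prepare_multirater_data(df, period)
    patterned = PatternedData(data.y, data.x, data.group)

    def params_from(theta: np.ndarray) -> MultiRaterParams:
        sq = theta[:9] ** 2
        e_floor = 1e-8
        return MultiRaterParams(
            common=AceParams(a2=sq[0], c2=sq[1], e2=max(sq[2], e_floor)),
            mother_specific=AceParams(a2=sq[3], c2=sq[4], e2=max(sq[5], e_floor)),
            father_specific=AceParams(a2=sq[6], c2=sq[7], e2=max(sq[8], e_floor)),
        )

    def neg2ll(theta: np.ndarray) -> float:
        p = params_from(theta)
        covs = [
            build_multirater_expected_cov(p, "MZ"),
            build_multirater_expected_cov(p, "DZ"),
        ]
        ll = patterned.loglik(covs, theta[9:])
        return np.inf if not np.isfinite(ll) else -2.0 * ll

    # moment start
    S = _sample_moments(data)
    Smz, Sdz = S[0], S[1]
    def _nz(v, lo=0.01):
        return lo if not np.isfinite(v) else max(v, lo)
    ct0 = _nz(np.nanmean([Smz[0, 1], Smz[2, 3], Sdz[0, 1], Sdz[2, 3]]), 0.05)
    mzcc = np.nanmean([Smz[0, 3], Smz[1, 2]])
    dzcc = np.nanmean([Sdz[0, 3], Sdz[1, 2]])
    if not (np.isfinite(mzcc) and np.isfinite(dzcc)):
        mzcc, dzcc = 0.6 * ct0, 0.45 * ct0
    a0 = _nz(2.0 * (mzcc - dzcc))
    c0 = _nz(2.0 * dzcc - mzcc)
    e0 = _nz(ct0 - a0 - c0, 0.02)
    start_specific = []
    for rater_cells, same_rater_cross in ((([0, 2]), (0, 2)), (([1, 3]), (1, 3))):
        var_r = _nz(np.nanmean([Smz[i, i] for i in rater_cells]
                               + [Sdz[i, i] for i in rater_cells]), 0.2)
        spec_tot = _nz(var_r - ct0, 0.05)
        mz_sr = np.nanmean([Smz[same_rater_cross]])
        dz_sr = np.nanmean([Sdz[same_rater_cross]])
        if not (np.isfinite(mz_sr) and np.isfinite(dz_sr)):
            mz_sr, dz_sr = mzcc + 0.5 * spec_tot, dzcc + 0.4 * spec_tot
        ar0 = _nz(2.0 * ((mz_sr - mzcc) - (dz_sr - dzcc)))
        cr0 = _nz(2.0 * (dz_sr - dzcc) - (mz_sr - mzcc))
        er0 = _nz(spec_tot - ar0 - cr0, 0.02)
        start_specific.extend([ar0, cr0, er0])
    comps0 = np.array([a0, c0, e0] + start_specific)
    mean_m = np.nanmean(np.concatenate([data.y[:, 0], data.y[:, 2]]))
    mean_f = np.nanmean(np.concatenate([data.y[:, 1], data.y[:, 3]]))
    if not np.isfinite(mean_f):
        mean_f = mean_m
    start = np.concatenate([np.sqrt(comps0), [mean_m, mean_f, 0.0, 0.0]])

    res = fit_model(neg2ll, start, n_restarts=n_restarts, seed=seed)
    params = params_from(res.x)
    comp_names = [
        "a2", "c2", "e2", "a2_m", "c2_m", "e2_m", "a2_f", "c2_f", "e2_f",
    ]
    values = [
        params.common.a2, params.common.c2, params.common.e2,
        params.mother_specific.a2, params.mother_specific.c2, params.mother_specific.e2,
        params.father_specific.a2, params.father_specific.c2, params.father_specific.e2,
    ]
    named = dict(zip(comp_names, map(float, values)))
    named.update(
        mean_mother=float(res.x[9]), mean_father=float(res.x[10]),
        beta_age=float(res.x[11]), beta_sex=float(res.x[12]),
    )
    flags = list(data.flags)
    flags.extend(f"component {n} at the zero boundary" for n, v in named.items()
                 if n in comp_names and v < 1e-4)
    fit = FitResult(
        params=named,
        minus2ll=float(res.fun),
        converged=bool(res.success),
        n_obs=patterned.n_obs,
        n_params=res.x.size,
        message=str(res.message),
        flags=flags,
    )
    return params, fit


# ---------------------------------------------------------------------------
# constrained saturated model
# ---------------------------------------------------------------------------


@dataclass
class ConstrainedSaturatedFit:
    """Per-zygosity covariance matrices under the rating-equality constraints."""

    cov_mz: np.ndarray
    cov_dz: np.ndarray
    means: np.ndarray  # [int_m, int_f, age, female]
    fit: FitResult
    fit_free: FitResult
    lrt_stat: float
    lrt_df: int
    lrt_p: float
    cross_rater_cov: float
    cross_rater_corr: float
    flags: list[str] = field(default_factory=list)


def _constrained_cov(v: np.ndarray) -> np.ndarray:
    """(vm, vf, cmm, cff, ccr) + shared cw -> symmetric 4x4."""
    vm, vf, cmm, cff, ccr, cw = v
    return np.array(
        [
            [vm, cw, cmm, ccr],
            [cw, vf, ccr, cff],
            [cmm, ccr, vm, cw],
            [ccr, cff, cw, vf],
        ]
    )


def fit_constrained_saturated(
    df: pd.DataFrame,
    period: str,
    *,
    n_restarts: int = 3,
    seed: int = 0,
    alpha: float = 0.05,
) -> ConstrainedSaturatedFit:
    """Fit per-zygosity 4x4 covariance matrices under the two equality
    constraint sets and test them against the unconstrained matrices.

    Constraints: (1) same-twin cross-rater covariance equal across zygosity
    (and twin order); (2) cross-twin cross-rater covariance equal across
    twin order within zygosity.  Variances are also equated across twin
    order (twin labelling is arbitrary).  The likelihood-ratio test against
    the free per-zygosity matrices has 9 degrees of freedom.
    """
    data = prepare_multirater_data(df, period)
    patterned = PatternedData(data.y, data.x, data.group)

    # --- constrained model: 11 covariance params + 4 means
    def neg2ll_con(theta: np.ndarray) -> float:
        mz = _constrained_cov(np.concatenate([theta[0:5], theta[10:11]]))
        dz = _constrained_cov(np.concatenate([theta[5:10], theta[10:11]]))
        ll = patterned.loglik([mz, dz], theta[11:])
        return np.inf if not np.isfinite(ll) else -2.0 * ll

    S = _sample_moments(data)
    def _f(v, d):
        return d if not np.isfinite(v) else v
    start_parts = []
    for g in (0, 1):
        Sg = S[g]
        vm = _f(np.nanmean([Sg[0, 0], Sg[2, 2]]), 1.0)
        vf = _f(np.nanmean([Sg[1, 1], Sg[3, 3]]), 1.0)
        cmm = _f(Sg[0, 2], 0.5 * vm)
        cff = _f(Sg[1, 3], 0.5 * vf)
        ccr = _f(np.nanmean([Sg[0, 3], Sg[1, 2]]), 0.2)
        start_parts.extend([vm, vf, cmm, cff, ccr])
    cw0 = _f(np.nanmean([S[0][0, 1], S[0][2, 3], S[1][0, 1], S[1][2, 3]]), 0.3)
    mean_m = np.nanmean(np.concatenate([data.y[:, 0], data.y[:, 2]]))
    mean_f = np.nanmean(np.concatenate([data.y[:, 1], data.y[:, 3]]))
    start_con = np.array(start_parts + [cw0, mean_m, mean_f, 0.0, 0.0])

    res_con = fit_model(neg2ll_con, start_con, n_restarts=n_restarts, seed=seed)
    fit_con = FitResult(
        params={
            **{f"mz_{n}": float(v) for n, v in zip(("vm", "vf", "cmm", "cff", "ccr"), res_con.x[0:5])},
            **{f"dz_{n}": float(v) for n, v in zip(("vm", "vf", "cmm", "cff", "ccr"), res_con.x[5:10])},
            "cross_rater_cov": float(res_con.x[10]),
        },
        minus2ll=float(res_con.fun),
        converged=bool(res_con.success),
        n_obs=patterned.n_obs,
        n_params=15,
        message=str(res_con.message),
    )

    # --- free model: per-zygosity Cholesky (10 each) + 4 means
    tril = np.tril_indices(4)

    def neg2ll_free(theta: np.ndarray) -> float:
        covs = []
        for g in range(2):
            L = np.zeros((4, 4))
            L[tril] = theta[g * 10 : (g + 1) * 10]
            covs.append(L @ L.T)
        ll = patterned.loglik(covs, theta[20:])
        return np.inf if not np.isfinite(ll) else -2.0 * ll

    start_free_parts = []
    for g in (0, 1):
        Sg = np.where(np.isfinite(S[g]), S[g], 0.0)
        Sg = 0.5 * (Sg + Sg.T)
        w, v = np.linalg.eigh(Sg)
        Sg = (v * np.clip(w, 0.05, None)) @ v.T
        start_free_parts.append(np.linalg.cholesky(Sg)[tril])
    start_free = np.concatenate(start_free_parts + [[mean_m, mean_f, 0.0, 0.0]])
    res_free = fit_model(neg2ll_free, start_free, n_restarts=n_restarts, seed=seed + 1)
    fit_free = FitResult(
        params={"minus2ll": float(res_free.fun)},
        minus2ll=float(res_free.fun),
        converged=bool(res_free.success),
        n_obs=patterned.n_obs,
        n_params=24,
        message=str(res_free.message),
    )

    stat, dfree, p = lrt(fit_free, fit_con)

    n_mz = int((data.group == 0).sum())
    n_dz = int((data.group == 1).sum())
    vm_bar = (n_mz * res_con.x[0] + n_dz * res_con.x[5]) / (n_mz + n_dz)
    vf_bar = (n_mz * res_con.x[1] + n_dz * res_con.x[6]) / (n_mz + n_dz)
    cw = float(res_con.x[10])
    corr = cw / np.sqrt(vm_bar * vf_bar)

    flags = list(data.flags)
    if p < alpha:
        flags.append(
            f"equality constraints rejected at alpha={alpha} (LRT p={p:.4g}); "
            "the constrained model is not parsimonious for these data"
        )
    return ConstrainedSaturatedFit(
        cov_mz=_constrained_cov(np.concatenate([res_con.x[0:5], res_con.x[10:11]])),
        cov_dz=_constrained_cov(np.concatenate([res_con.x[5:10], res_con.x[10:11]])),
        means=res_con.x[11:].copy(),
        fit=fit_con,
        fit_free=fit_free,
        lrt_stat=stat,
        lrt_df=dfree,
        lrt_p=p,
        cross_rater_cov=cw,
        cross_rater_corr=float(corr),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# view decomposition
# ---------------------------------------------------------------------------


@dataclass
class ViewDecomposition:
    """Common-view vs rater-specific decomposition of rating variance.

    ``common_share_pooled`` counts the common phenotype once against the
    union of distinct variance sources (common + mother-specific +
    father-specific); the per-rater shares decompose each parent's total
    rated variance.  ``bias_index`` is the rater-specific shared-environment
    (rater bias) share of that rater's total variance.
    """

    common_share_pooled: float
    per_rater: dict[str, dict[str, float]]
    bias_index: dict[str, float]


def decompose_views(params: MultiRaterParams) -> ViewDecomposition:
    com = params.common
    ct = com.total
    out: dict[str, dict[str, float]] = {}
    bias: dict[str, float] = {}
    for rater, spec in (("mother", params.mother_specific), ("father", params.father_specific)):
        total = ct + spec.total
        if total <= 0:
            raise ValueError("zero total rated variance; decomposition undefined")
        shares = {
            "common": ct / total,
            "specific": spec.total / total,
            "common_a2": com.a2 / total,
            "common_c2": com.c2 / total,
            "common_e2": com.e2 / total,
            "specific_a2": spec.a2 / total,
            "specific_c2": spec.c2 / total,
            "specific_e2": spec.e2 / total,
        }
        out[rater] = shares
        bias[rater] = shares["specific_c2"]
    pooled_denom = ct + params.mother_specific.total + params.father_specific.total
    return ViewDecomposition(
        common_share_pooled=ct / pooled_denom,
        per_rater=out,
        bias_index=bias,
    )
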