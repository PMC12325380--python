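"""Random-intercept linear mixed models for mean wellbeing trends.

The trend model is ``Y = (b1 + u) + b2*wave + b3*sex + b4*age + b5*PEA +
b6*rater + e`` with wave categorical against a reference wave, female vs
male, three-level parental educational attainment (low/middle vs high) and
father vs mother rater.  Random intercepts are either absent, per
individual, or per individual nested within family (the twin design).
Estimation is maximum likelihood on the marginal Gaussian likelihood with
the fixed effects profiled out by GLS; the per-family marginal covariance
is ``var_family*J + var_individual*blockdiag(J) + var_residual*I``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import LmmFit

__all__ = [
    "build_design",
    "fit_random_intercept_lmm",
    "estimated_marginal_means",
    "select_baseline",
]

NESTINGS = ("none", "individual", "individual-in-family")


def build_design(
    rows: pd.DataFrame, *, ref_wave: int | None = None
) -> tuple[np.ndarray, list[str], int]:
    """Fixed-effect design matrix with reference levels: reference wave
    (default = earliest present), male, high PEA, mother rater."""
    waves = sorted(int(w) for w in rows["wave"].unique())
    ref = int(ref_wave) if ref_wave is not None else waves[0]
    if ref not in waves:
        raise ValueError(f"reference wave {ref} not present in data")
    cols = ["intercept"]
    mats = [np.ones(len(rows))]
    for w in waves:
        if w == ref:
            continue
        cols.append(f"wave_{w}")
        mats.append((rows["wave"].to_numpy() == w).astype(float))
    cols += ["female", "age", "pea_low", "pea_middle", "father"]
    mats += [
        (rows["sex"].to_numpy() == "F").astype(float),
        rows["age"].to_numpy(dtype=float),
        (rows["pea"].to_numpy() == "low").astype(float),
        (rows["pea"].to_numpy() == "middle").astype(float),
        (rows["rater"].to_numpy() == "father").astype(float),
    ]
    X = np.column_stack(mats)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name aliased columns via pivoted QR
        _, _, piv = _qr_pivot(X)
        aliased = [cols[j] for j in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")
    return X, cols, ref


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    return qr(X, pivoting=True, mode="economic")


def _group_structures(rows: pd.DataFrame, nesting: str):
    """Bucket families by their (individual observation count) signature.

    Rows must be pre-sorted by family then individual; the marginal
    covariance of a family depends only on how many observations each of
    its members contributes.
    """
    fam = rows["family_id"].to_numpy()
    ind = rows["individual_id"].to_numpy()
    n = len(rows)
    fam_change = np.r_[True, fam[1:] != fam[:-1]]
    fam_starts = np.flatnonzero(fam_change)
    fam_ends = np.r_[fam_starts[1:], n]
    buckets: dict[tuple[int, ...], list[np.ndarray]] = {}
    for s, e in zip(fam_starts, fam_ends):
        sizes = []
        last = None
        cnt = 0
        for i in range(s, e):
            if ind[i] != last:
                if last is not None:
                    sizes.append(cnt)
                last = ind[i]
                cnt = 0
            cnt += 1
        sizes.append(cnt)
        buckets.setdefault(tuple(sizes), []).append(np.arange(s, e))
    return buckets


def _sigma_for_signature(sig: tuple[int, ...], vf: float, vi: float, ve: float) -> np.ndarray:
    k = sum(sig)
    S = np.full((k, k), vf)
    pos = 0
    for m in sig:
        S[pos : pos + m, pos : pos + m] += vi
        pos += m
    S[np.diag_indices(k)] += ve
    return S


def fit_random_intercept_lmm(
    rows: pd.DataFrame,
    *,
    nesting: str = "individual-in-family",
    ref_wave: int | None = None,
) -> LmmFit:
    """ML fit of the random-intercept trend model.

    ``nesting='none'`` reduces to ordinary least squares; ``'individual'``
    adds an individual intercept (families ignored); ``'individual-in-
    family'`` nests individuals within family, giving twins of a family the
    covariance ``var_family`` and repeated observations of one child
    ``var_family + var_individual``.
    """
    if nesting not in NESTINGS:
        raise ValueError(f"nesting must be one of {NESTINGS}")
    rows = rows.sort_values(["family_id", "individual_id", "wave"], kind="stable")
    rows = rows.reset_index(drop=True)
    if rows["wellbeing"].isna().any():
        raise ValueError("wellbeing must be observed on every row")
    X, cols, ref = build_design(rows, ref_wave=ref_wave)
    y = rows["wellbeing"].to_numpy(dtype=float)
    n, p = X.shape

    if nesting == "individual":
        # treat each individual as its own family; family variance absorbed
        rows = rows.assign(family_id=rows["individual_id"])

    buckets = _group_structures(rows, nesting)
    packs = []
    for sig, idx_list in buckets.items():
        idx = np.stack(idx_list)
        packs.append((sig, idx, y[idx], X[idx]))

    def variances(theta: np.ndarray) -> tuple[float, float, float]:
        v = np.exp(theta)
        if nesting == "none":
            return 0.0, 0.0, float(v[0])
        if nesting == "individual":
            return 0.0, float(v[0]), float(v[1])
        return float(v[0]), float(v[1]), float(v[2])

    def profiled(theta: np.ndarray, want_beta: bool = False):
        vf, vi, ve = variances(theta)
        A = np.zeros((p, p))
        b = np.zeros(p)
        yty = 0.0
        logdet = 0.0
        for sig, idx, yg, Xg in packs:
            S = _sigma_for_signature(sig, vf, vi, ve)
            try:
                L = np.linalg.cholesky(S)
            except np.linalg.LinAlgError:
                return (np.inf, None, None) if want_beta else np.inf
            logdet += 2.0 * np.log(np.diag(L)).sum() * idx.shape[0]
            Si = np.linalg.inv(S)
            A += np.einsum("mkp,kl,mlq->pq", Xg, Si, Xg, optimize=True)
            b += np.einsum("mkp,kl,ml->p", Xg, Si, yg, optimize=True)
            yty += float(np.einsum("mk,kl,ml->", yg, Si, yg, optimize=True))
        beta = np.linalg.solve(A, b)
        quad = yty - 2.0 * beta @ b + beta @ A @ beta
        neg2 = n * np.log(2.0 * np.pi) + logdet + quad
        if want_beta:
            return neg2, beta, A
        return neg2

    var_y = float(np.var(y))
    if nesting == "none":
        theta0 = np.array([np.log(var_y)])
    elif nesting == "individual":
        theta0 = np.log([0.5 * var_y, 0.5 * var_y])
    else:
        theta0 = np.log([var_y / 3, var_y / 3, var_y / 3])

    res = optimize.minimize(profiled, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
    neg2, beta, A = profiled(res.x, want_beta=True)
    vf, vi, ve = variances(res.x)
    cov_beta = np.linalg.inv(A)
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    dof = max(n - p, 1)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)

    flags = []
    max_obs = rows.groupby("individual_id").size().max()
    if nesting != "none" and max_obs == 1:
        flags.append(
            "one observation per individual: individual and residual variances "
            "are not separately identified (only their sum)"
        )

    return LmmFit(
        beta=dict(zip(cols, map(float, beta))),
        se=dict(zip(cols, map(float, se))),
        tstat=dict(zip(cols, map(float, tvals))),
        pvalue=dict(zip(cols, map(float, pvals))),
        var_family=vf,
        var_individual=vi,
        var_residual=ve,
        loglik=-0.5 * float(neg2),
        n_obs=n,
        n_individuals=rows["individual_id"].nunique(),
        n_families=rows["family_id"].nunique(),
        nesting=nesting,
        ref_wave=ref,
        design_columns=cols,
        design_mean=X.mean(axis=0),
        flags=flags,
    )


def estimated_marginal_means(fit: LmmFit, waves=None) -> pd.Series:
    """Model-predicted mean per wave at covariate values averaged over the
    sample (sex/PEA/rater at observed proportions, age at its mean)."""
    wave_cols = [c for c in fit.design_columns if c.startswith("wave_")]
    known = sorted([fit.ref_wave] + [int(c.split("_")[1]) for c in wave_cols])
    if waves is None:
        waves = known
    out = {}
    beta = np.array([fit.beta[c] for c in fit.design_columns])
    for w in waves:
        if int(w) not in known:
            raise ValueError(f"wave {w} absent from the fitted data")
        x = fit.design_mean.copy()
        for c in wave_cols:
            x[fit.design_columns.index(c)] = 1.0 if c == f"wave_{int(w)}" else 0.0
        out[int(w)] = float(x @ beta)
    return pd.Series(out, name="emm").sort_index()


def select_baseline(rows: pd.DataFrame) -> pd.Series | None:
    """Latest pre-pandemic record for one individual.

    Pre-pandemic rows are wave 0 (or period 'pre'); recency is judged by a
    'year' column when present, else by wave.  Ties resolve
    deterministically to the first record in input order.
    """
    pre = rows[rows["wave"] == 0] if "wave" in rows.columns else rows[rows["period"] == "pre"]
    if "period" in rows.columns and "wave" in rows.columns:
        pre = rows[(rows["wave"] == 0) | (rows["period"] == "pre")]
    if pre.empty:
        return None
    key = pre["year"] if "year" in pre.columns else pre["wave"]
    best = key.to_numpy().argmax()  # argmax returns the first maximal entry
    return pre.iloc[best]
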