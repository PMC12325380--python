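"""Raw-data (full-information) multivariate-normal likelihood.

Families are independent sampling units; each contributes the density of the
multivariate normal restricted to its observed variables.  Families are
bucketed once by (covariance group, missingness pattern); repeated
likelihood evaluations reuse the bookkeeping, batch the Cholesky factors of
all observed submatrices of a given size, and evaluate the quadratic forms
with a single flattened design product, so cohorts with hundreds of
missing-data patterns remain cheap to iterate over.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class _Bucket:
    group: int
    cols: np.ndarray  # observed variable indices (k_obs,)
    rows: np.ndarray  # family indices in this bucket
    offset: int  # start into the flattened data vector
    m: int  # families in bucket
    k: int  # observed variables per family


class PatternedData:
    """Data for FIML evaluation, grouped by missingness pattern.

    Parameters
    ----------
    y:
        ``(n_families, k)`` outcome matrix with NaN marking unobserved cells.
    x:
        ``(n_families, k, p)`` design tensor; the model-implied mean of family
        ``f`` is ``x[f] @ beta``.
    group:
        ``(n_families,)`` integer codes selecting which expected covariance
        matrix applies (e.g. 0 = MZ, 1 = DZ).
    """

    def __init__(self, y: np.ndarray, x: np.ndarray, group: np.ndarray):
        y = np.asarray(y, dtype=float)
        x = np.asarray(x, dtype=float)
        group = np.asarray(group)
        if y.ndim != 2 or x.shape[:2] != y.shape or group.shape != (y.shape[0],):
            raise ValueError("inconsistent shapes for y, x, group")
        obs = np.isfinite(y)
        if not obs.any(axis=1).all():
            raise ValueError("every family must have at least one observed variable")
        self.k = y.shape[1]
        self.n_families = y.shape[0]
        self.n_obs = int(obs.sum())
        self.p = x.shape[2]

        codes = group.astype(np.int64) * (2**self.k) + obs.dot(1 << np.arange(self.k))
        order = np.argsort(codes, kind="stable")
        boundaries = np.flatnonzero(np.diff(codes[order])) + 1
        raw = [
            (int(group[rows[0]]), np.flatnonzero(obs[rows[0]]), rows)
            for rows in np.split(order, boundaries)
        ]
        # order buckets by pattern size so cholesky factors batch per size
        raw.sort(key=lambda t: t[1].size)

        self.buckets: list[_Bucket] = []
        y_parts, x_parts = [], []
        offset = 0
        for g, cols, rows in raw:
            m, kk = rows.size, cols.size
            yb = y[np.ix_(rows, cols)]
            xb = x[np.ix_(rows, cols)]
            y_parts.append(yb.ravel())
            x_parts.append(xb.reshape(m * kk, self.p))
            self.buckets.append(_Bucket(g, cols, rows, offset, m, kk))
            offset += m * kk
        self._y_flat = np.concatenate(y_parts)
        self._x_flat = np.vstack(x_parts)
        # size groups: slices of consecutive buckets sharing k
        self._size_groups: list[tuple[int, int, int]] = []  # (k, first, last)
        i = 0
        while i < len(self.buckets):
            j = i
            while j < len(self.buckets) and self.buckets[j].k == self.buckets[i].k:
                j += 1
            self._size_groups.append((self.buckets[i].k, i, j))
            i = j

    @staticmethod
    def _indefinite_penalty(sub: np.ndarray) -> float:
        """Finite, sloped log-likelihood penalty for indefinite submatrices.

        A hard ``-inf`` barrier starves line searches of gradient
        information and can stall quasi-Newton optimizers one step from a
        feasible start; instead the penalty grows with the total negative
        eigenvalue mass, pointing back toward the PD region.
        """
        try:
            w = np.linalg.eigvalsh(sub)
        except np.linalg.LinAlgError:
            return -1e12
        if not np.all(np.isfinite(w)):
            return -1e12
        violation = float(np.clip(w, None, 0.0).sum())
        return -1e10 * (1.0 - violation)

    def loglik(self, covs, beta: np.ndarray) -> float:
        """Sum of observed-data log densities; a large finite penalty
        (see :meth:`_indefinite_penalty`) if any observed submatrix of an
        expected covariance is not positive definite."""
        covarr = np.asarray(covs, dtype=float)
        beta = np.asarray(beta, dtype=float)
        resid = self._y_flat - self._x_flat @ beta

        total = 0.0
        for kk, i0, i1 in self._size_groups:
            bs = self.buckets[i0:i1]
            gc = np.array([b.group for b in bs])
            cols = np.stack([b.cols for b in bs])
            sub = covarr[gc[:, None, None], cols[:, :, None], cols[:, None, :]]
            try:
                chol = np.linalg.cholesky(sub)
            except np.linalg.LinAlgError:
                return self._indefinite_penalty(sub)
            diag = np.diagonal(chol, axis1=1, axis2=2)
            if not np.all(diag > 0):
                return self._indefinite_penalty(sub)
            logdets = 2.0 * np.log(diag).sum(axis=1)
            linv = np.linalg.inv(chol)
            for b, ld, li in zip(bs, logdets, linv):
                r = resid[b.offset : b.offset + b.m * b.k].reshape(b.m, b.k)
                z = r @ li.T
                total += -0.5 * (
                    b.m * (b.k * _LOG2PI + ld) + float(np.square(z).sum())
                )
        return total


def fiml_loglik(y: np.ndarray, mu: np.ndarray, covs, group: np.ndarray) -> float:
    """One-shot observed-data log-likelihood.

    ``mu`` is the ``(n_families, k)`` matrix of model-implied means; missing
    cells of ``y`` (NaN) are marginalized out by submatrix selection, which
    is exactly the marginal normal density of the observed subvector.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    x = mu[:, :, None]
    return PatternedData(y, x, group).loglik(covs, np.ones(1))
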