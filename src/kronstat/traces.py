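"""Unbiased U-statistic estimators of covariance trace functionals.

For transposable data X_1, ..., X_N (r x c matrices) with Kronecker
covariance Cov(X_ij, X_lm) = (Sigma_R)_il (Sigma_C)_jm, the row and column
covariance matrices are only identified up to a scale swap
(a Sigma_C, Sigma_R / a).  We adopt the convention tr(Sigma_C) = c, so each
column (tissue) has average unit scale and row-side functionals are
absolutely identified.

All estimators are built from scaled pair differences
D_ij = (X_i - X_j) / sqrt(2), which are mean-free with the same Kronecker
covariance as X, and average kernels over *distinct subject quadruples* so
that the two pair differences entering a product are independent.  For the
row side this yields exactly unbiased estimates of

    t1 = tr(Sigma_R), t2 = tr(Sigma_R^2), t3 = tr^2(Sigma_R),
    t4 = sum_a (Sigma_R)_aa^2.

Column-side functionals are only identified relative to the row scale, so
they are reported as scale-free ratios under the trace convention:
t1 = c exactly, t3 = c^2 exactly, and t2 (resp. t4) is c^2 times the ratio
of the quadruple-average of tr(W_p W_q) (resp. of the diagonal products) to
the quadruple-average of tr(W_p) tr(W_q), with W_p = D_p' D_p.  These
ratios are consistent, though not exactly unbiased, for tr(Sigma_C^2) and
sum_j (Sigma_C)_jj^2.

A literal O(N^4) enumeration oracle of the same definitions is provided for
verification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._pairs import (
    disjoint_pair_count,
    disjoint_pair_mask,
    disjoint_feature_sum,
    masked_quad_mean,
    pair_indices,
)
from .data import TransposableDataset

__all__ = [
    "TraceFunctionals",
    "pair_difference",
    "trace_functionals",
    "trace_functionals_oracle",
]


@dataclass(frozen=True)
class TraceFunctionals:
    """Estimated trace functionals of one side's covariance matrix.

    Attributes
    ----------
    side : "rows" or "columns"
    p : dimension of the estimated covariance (r or c)
    t1, t2, t3, t4 : estimates of tr(Sigma), tr(Sigma^2), tr^2(Sigma) and
        sum_j Sigma_jj^2 under the tr(Sigma_C) = c convention
    n_subjects : number of subjects the estimates are based on
    """

    side: str
    p: int
    t1: float
    t2: float
    t3: float
    t4: float
    n_subjects: int


def pair_difference(ds: TransposableDataset, i: int, j: int) -> np.ndarray:
    """Scaled difference (X_i - X_j)/sqrt(2) of two subjects' matrices.

    Mean-free regardless of M, with the same Kronecker covariance as X.
    """
    if i == j:
        raise ValueError("pair_difference requires two distinct subjects")
    return (ds.values[i] - ds.values[j]) / math.sqrt(2.0)


def _require(ds: TransposableDataset, side: str) -> None:
    if side not in ("rows", "columns"):
        raise ValueError(f"side must be 'rows' or 'columns', got {side!r}")
    if ds.n_subjects < 4:
        raise ValueError(
            "insufficient subjects for quadruple U-statistics (need N >= 4, "
            f"got N = {ds.n_subjects})"
        )
    if not np.all(np.isfinite(ds.values)):
        raise ValueError("non-finite values in dataset")


def _pair_diffs(x: np.ndarray, I: np.ndarray, J: np.ndarray) -> np.ndarray:
    return (x[I] - x[J]) / math.sqrt(2.0)


def _quad_means_small_gram(d: np.ndarray, n: int, side: str) -> tuple[float, float, float]:
    """Quadruple means (q2, q3, q4) via the feature identity, O(P) space.

    Every kernel is an inner product of per-pair features: q2 uses the pair
    Gram (D_p D_p' for rows, D_p' D_p for columns), q3 its trace and q4 its
    diagonal, so the disjoint-pair sums collapse to subject totals.
    """
    cnt = disjoint_pair_count(n)
    gram = np.einsum("prc,psc->prs", d, d) if side == "rows" else np.einsum("prc,prd->pcd", d, d)
    q2 = disjoint_feature_sum(gram, n) / cnt
    trg = np.trace(gram, axis1=1, axis2=2)
    q3 = disjoint_feature_sum(trg[:, None], n) / cnt
    diag = np.ascontiguousarray(np.diagonal(gram, axis1=1, axis2=2))
    q4 = disjoint_feature_sum(diag, n) / cnt
    return q2, q3, q4


def _row_quad_means_large_r(
    x: np.ndarray, d: np.ndarray, I: np.ndarray, J: np.ndarray, chunk: int = 64
) -> tuple[float, float, float]:
    """Row-side quadruple means when the r x r pair Grams are too large to
    stack: (P, P) kernels from the subject cross-Gram tensor
    C[a,b] = X_a' X_b (c x c), chunked over pairs."""
    P = len(I)
    mask = disjoint_pair_mask(I, J)
    w = np.einsum("prc,prc->p", d, d)  # tr(D_p D_p')
    rss = np.einsum("prc,prc->pr", d, d)  # per-row sums of squares
    ct = np.einsum("arc,brd->abcd", x, x)  # (N, N, c, c)
    m2 = np.empty((P, P))
    for s in range(0, P, chunk):
        e = min(s + chunk, P)
        ii, jj = I[s:e], J[s:e]
        # G[p, q] = D_p' D_q = (C[i,k] - C[i,l] - C[j,k] + C[j,l]) / 2
        g = 0.5 * (ct[ii][:, I] - ct[ii][:, J] - ct[jj][:, I] + ct[jj][:, J])
        m2[s:e] = np.einsum("pqcd,pqcd->pq", g, g)
    q2 = masked_quad_mean(m2, mask)
    q3 = masked_quad_mean(np.outer(w, w), mask)
    q4 = masked_quad_mean(rss @ rss.T, mask)
    return q2, q3, q4


_FEATURE_BYTES_CAP = 2e8  # stack P pair Grams directly below this footprint


def trace_functionals(ds: TransposableDataset, side: str) -> TraceFunctionals:
    """Estimate (t1, t2, t3, t4) for the row or column covariance.

    Row side: exactly unbiased distinct-quadruple U-statistics under the
    tr(Sigma_C) = c convention.  Column side: t1 = c and t3 = c^2 by
    normalization; t2, t4 are scale-free consistent ratio estimates.
    Requires N >= 4.
    """
    _require(ds, side)
    x = ds.values
    n, r, c = x.shape
    I, J = pair_indices(n)
    d = _pair_diffs(x, I, J)
    if side == "rows":
        if len(I) * r * r * 8 <= _FEATURE_BYTES_CAP:
            q2, q3, q4 = _quad_means_small_gram(d, n, "rows")
        else:
            q2, q3, q4 = _row_quad_means_large_r(x, d, I, J)
        t1 = float(np.einsum("prc,prc->", d, d) / len(I) / c)
        return TraceFunctionals("rows", r, t1, q2 / c**2, q3 / c**2, q4 / c**2, n)
    q2, q3, q4 = _quad_means_small_gram(d, n, "columns")
    if q3 <= 0:
        raise ValueError("degenerate data: zero total variance on the column side")
    return TraceFunctionals("columns", c, float(c), c**2 * q2 / q3, float(c**2), c**2 * q4 / q3, n)


def trace_functionals_oracle(ds: TransposableDataset, side: str) -> TraceFunctionals:
    """Literal O(N^4) enumeration of the same trace functionals.

    Loops over every ordered subject quadruple (i, j, k, l) with all four
    indices distinct; intended as an independent correctness oracle for
    small N (<= 12).
    """
    _require(ds, side)
    if ds.n_subjects > 12:
        raise ValueError("oracle enumeration is O(N^4); use N <= 12")
    x = ds.values
    n, r, c = x.shape
    s1 = s2 = s3 = s4 = 0.0
    npairs = 0
    for i in range(n):
        for j in range(n):
            if j == i:
                continue
            dij = (x[i] - x[j]) / math.sqrt(2.0)
            gij = dij @ dij.T if side == "rows" else dij.T @ dij
            if i < j:
                s1 += np.trace(gij)
                npairs += 1
            for k in range(n):
                if k in (i, j):
                    continue
                for l in range(n):
                    if l in (i, j, k):
                        continue
                    dkl = (x[k] - x[l]) / math.sqrt(2.0)
                    gkl = dkl @ dkl.T if side == "rows" else dkl.T @ dkl
                    s2 += np.trace(gij @ gkl)
                    s3 += np.trace(gij) * np.trace(gkl)
                    s4 += float(np.diag(gij) @ np.diag(gkl))
    nquad = n * (n - 1) * (n - 2) * (n - 3)
    q2, q3, q4 = s2 / nquad, s3 / nquad, s4 / nquad
    if side == "rows":
        return TraceFunctionals("rows", r, s1 / npairs / c, q2 / c**2, q3 / c**2, q4 / c**2, n)
    if q3 <= 0:
        raise ValueError("degenerate data: zero total variance on the column side")
    return TraceFunctionals("columns", c, float(c), c**2 * q2 / q3, float(c**2), c**2 * q4 / q3, n)
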