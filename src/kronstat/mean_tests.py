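"""Mean-matrix estimation and high-dimensional mean-conservation tests.

The hypothesis of interest is that the mean expression profile is constant
across all columns, or within pre-specified column (tissue) groups:
H0: M P = 0, where P is the block-diagonal centering projection of the
grouping (I_k - J_k/k per group of size k).  The test statistic is the
projection U-statistic

    T = (1 / (N(N-1))) sum_{i != j} tr(X_i P X_j'),

which is exactly unbiased for tr(M P M') >= 0 and mean-free under H0
because independent subjects enter each summand.  Its null variance is
2 theta / (N(N-1)) with theta = tr((P Sigma_C)^2) tr(Sigma_R^2), estimated
unbiasedly by averaging [tr(D_ij P D_kl')]^2 over distinct subject
quadruples (D = scaled pair differences).  The standardized score is
referred to the standard normal, one-sided: large T is evidence against
conservation.  Validity rests on r >> N asymptotics, not on Gaussianity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from ._pairs import disjoint_pair_mask, masked_quad_mean, pair_indices
from .data import TransposableDataset, subset

__all__ = [
    "MeanMatrix",
    "ColumnGrouping",
    "TestResult",
    "estimate_mean",
    "make_projection",
    "mean_conservation_test",
    "mean_variance_term_oracle",
    "pairwise_conservation_tests",
    "bh_adjust",
]


@dataclass(frozen=True)
class MeanMatrix:
    """Labelled r x c estimate of the mean matrix M."""

    matrix: np.ndarray
    row_ids: list[str]
    col_ids: list[str]


@dataclass
class ColumnGrouping:
    """Ordered partition of column labels into disjoint nonempty groups.

    The associated null hypothesis is that the mean profile is constant
    within each group.
    """

    groups: list[list[str]]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("grouping needs at least one group")
        seen: set[str] = set()
        for g in self.groups:
            if not g:
                raise ValueError("empty group in column grouping")
            for x in g:
                if x in seen:
                    raise ValueError(f"column {x!r} appears in more than one group")
                seen.add(x)

    @property
    def columns(self) -> list[str]:
        return [x for g in self.groups for x in g]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test: raw statistic, standardized score z,
    one-sided p-value and a human-readable hypothesis descriptor."""

    statistic: float
    z: float
    p_value: float
    hypothesis: str
    details: dict = field(default_factory=dict)


def estimate_mean(ds: TransposableDataset) -> MeanMatrix:
    """Subject average Xbar = (1/N) sum_i X_i, the natural estimate of M."""
    return MeanMatrix(ds.values.mean(axis=0), list(ds.row_ids), list(ds.col_ids))


def make_projection(grouping: ColumnGrouping) -> np.ndarray:
    """Block-diagonal centering projection P of a column grouping.

    For a group of size k the block is I_k - J_k/k; P is symmetric,
    idempotent, with rank = (#columns) - (#groups).  M P = 0 iff M is
    constant within every group.
    """
    sizes = [len(g) for g in grouping.groups]
    c = sum(sizes)
    p = np.zeros((c, c))
    at = 0
    for k in sizes:
        p[at : at + k, at : at + k] = np.eye(k) - np.full((k, k), 1.0 / k)
        at += k
    return p


def _pair_diffs(x: np.ndarray, I: np.ndarray, J: np.ndarray) -> np.ndarray:
    return (x[I] - x[J]) / math.sqrt(2.0)


def mean_conservation_test(ds: TransposableDataset, grouping: ColumnGrouping) -> TestResult:
    """Test H0: mean profile constant within each column group.

    Columns not named by the grouping are ignored.  Requires N >= 4 and a
    non-vacuous grouping (at least one group of size >= 2).
    """
    if all(len(g) == 1 for g in grouping.groups):
        raise ValueError("vacuous hypothesis: every group is a singleton (P = 0)")
    sub = subset(ds, cols=grouping.columns)
    n = sub.n_subjects
    if n < 4:
        raise ValueError("mean_conservation_test requires N >= 4 subjects")
    p = make_projection(grouping)
    x = sub.values
    total = x.sum(axis=0)
    # sum_{i != j} tr(X_i P X_j') = tr(S P S') - sum_i tr(X_i P X_i')
    xp = np.einsum("irc,cd->ird", x, p)
    t_stat = (float(np.einsum("rc,rc->", total @ p, total)) - float(np.einsum("ird,ird->", xp, x))) / (
        n * (n - 1)
    )
    I, J = pair_indices(n)
    d = _pair_diffs(x, I, J)
    dp = np.einsum("prc,cd->prd", d, p).reshape(len(I), -1)
    theta_kernel = (dp @ d.reshape(len(I), -1).T) ** 2
    theta = masked_quad_mean(theta_kernel, disjoint_pair_mask(I, J))
    var = 2.0 * theta / (n * (n - 1))
    z = t_stat / math.sqrt(var) if var > 0 else math.inf
    groups_txt = " | ".join(",".join(g) for g in grouping.groups)
    return TestResult(
        statistic=t_stat,
        z=float(z),
        p_value=float(norm.sf(z)),
        hypothesis=f"mean profile constant within column groups [{groups_txt}]",
        details={
            "groups": [list(g) for g in grouping.groups],
            "theta": theta,
            "variance": var,
            "n_subjects": n,
            "n_rows": sub.n_rows,
        },
    )


def mean_variance_term_oracle(ds: TransposableDataset, grouping: ColumnGrouping) -> float:
    """Literal O(N^4) enumeration of the variance term theta =
    avg over distinct quadruples of [tr(D_ij P D_kl')]^2 (verification
    oracle; N <= 12)."""
    sub = subset(ds, cols=grouping.columns)
    x = sub.values
    n = sub.n_subjects
    if n < 4:
        raise ValueError("need N >= 4")
    if n > 12:
        raise ValueError("oracle enumeration is O(N^4); use N <= 12")
    p = make_projection(grouping)
    tot = 0.0
    cnt = 0
    for i in range(n):
        for j in range(n):
            if j == i:
                continue
            dij = (x[i] - x[j]) / math.sqrt(2.0)
            for k in range(n):
                if k in (i, j):
                    continue
                for l in range(n):
                    if l in (i, j, k):
                        continue
                    dkl = (x[k] - x[l]) / math.sqrt(2.0)
                    tot += np.trace(dij @ p @ dkl.T) ** 2
                    cnt += 1
    return tot / cnt


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.ndim != 1 or pvals.size == 0:
        raise ValueError("bh_adjust expects a nonempty 1-d list of p-values")
    if np.any((pvals < 0) | (pvals > 1) | ~np.isfinite(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def pairwise_conservation_tests(
    ds: TransposableDataset,
    row_subset,
    reference_col: str,
    other_cols=None,
) -> tuple[list[TestResult], np.ndarray]:
    """Mean-conservation tests between a reference column and each other
    column, on a row subset (e.g. a tissue-specific gene list), with BH
    adjustment across the family.

    Returns the per-column results (each carrying its adjusted p-value in
    ``details["p_adj"]``) and the adjusted p-value array in family order.
    """
    if other_cols is None:
        other_cols = [x for x in ds.col_ids if x != reference_col]
    other_cols = [str(x) for x in other_cols]
    if reference_col in other_cols:
        raise ValueError(f"reference column {reference_col!r} also listed in other_cols")
    if not other_cols:
        raise ValueError("no comparison columns")
    results = []
    for f in other_cols:
        sub = subset(ds, rows=row_subset, cols=[reference_col, f])
        res = mean_conservation_test(sub, ColumnGrouping([[reference_col, f]]))
        results.append(res)
    adj = bh_adjust([t.p_value for t in results])
    out = []
    for res, f, a in zip(results, other_cols, adj):
        det = dict(res.details)
        det.update({"reference": reference_col, "other": f, "p_adj": float(a)})
        out.append(
            TestResult(
                res.statistic,
                res.z,
                res.p_value,
                f"mean profile of row subset conserved between {reference_col} and {f}",
                det,
            )
        )
    return out, adj
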