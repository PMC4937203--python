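"""Sample and Stein-type shrinkage estimators of the row/column covariance.

With far more genes than subjects (r >> N) the sample covariance of the
rows is singular and badly conditioned.  The estimators here mix the
sample covariance S with a structured target T,

    Sigma_hat = (1 - lambda) * S + lambda * T,

with a data-driven intensity lambda in [0, 1] chosen to minimize expected
Frobenius loss; the required moments tr(Sigma), tr(Sigma^2), tr^2(Sigma)
and sum_j Sigma_jj^2 are plugged in from the unbiased U-statistics of
:mod:`kronstat.traces`.  Three targets are supported: ``spherical``
((tr S / p) I), ``identity`` (I) and ``diagonal`` (diag(S)).  For any
positive-definite target and lambda > 0 the output is positive definite,
hence invertible, regardless of dimension.

Column-side estimates are kept on the tr(Sigma_C) = c identifiability
convention: the sample estimate is rescaled to trace c, and shrinkage
output is renormalized to trace c after mixing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TransposableDataset
from .traces import TraceFunctionals, trace_functionals

__all__ = [
    "CovarianceEstimate",
    "sample_covariance",
    "shrinkage_intensity",
    "shrink_covariance",
    "correlation_from_covariance",
]


@dataclass
class CovarianceEstimate:
    """A (possibly shrunk) covariance estimate for one side.

    ``intensity`` is the shrinkage weight lambda (0 for the raw sample
    estimate); ``normalization`` records the identifiability convention in
    force ("tr(Sigma_C)=c" on the column side).
    """

    side: str
    matrix: np.ndarray
    target: str
    intensity: float
    normalization: str
    ids: list[str]


def _normalization_note(side: str) -> str:
    return "tr(Sigma_C)=c" if side == "columns" else "rows identified via tr(Sigma_C)=c"


def sample_covariance(ds: TransposableDataset, side: str) -> CovarianceEstimate:
    """Sample covariance of the rows or columns.

    rows:    S_R = sum_i (X_i - Xbar)(X_i - Xbar)' / ((N - 1) c), unbiased
             for Sigma_R under the trace convention;
    columns: sum_i (X_i - Xbar)'(X_i - Xbar) / (N - 1), rescaled to trace c.
    """
    if side not in ("rows", "columns"):
        raise ValueError(f"side must be 'rows' or 'columns', got {side!r}")
    n, r, c = ds.values.shape
    if n < 2:
        raise ValueError("sample covariance requires N >= 2")
    y = ds.values - ds.values.mean(axis=0)
    if side == "rows":
        s = np.einsum("irc,ilc->rl", y, y) / ((n - 1) * c)
        ids = list(ds.row_ids)
    else:
        s = np.einsum("irc,irl->cl", y, y) / (n - 1)
        tr = np.trace(s)
        if tr <= 0:
            raise ValueError("zero total variance: cannot normalize column covariance")
        s = s * (c / tr)
        ids = list(ds.col_ids)
    return CovarianceEstimate(side, s, "none", 0.0, _normalization_note(side), ids)


def shrinkage_intensity(tf: TraceFunctionals, target: str) -> float:
    """Frobenius-optimal shrinkage weight from plug-in trace functionals.

    The closed forms below come from minimizing E||(1-l) S + l T - Sigma||_F^2
    with the unknown moments replaced by the unbiased quadruple
    U-statistics (t3 is the dedicated unbiased estimate of tr^2(Sigma), not
    t1^2).  The result is truncated to [0, 1]; a nonpositive denominator
    signals data already inside the target family and maps to l = 1.
    """
    t1, t2, t3, t4 = tf.t1, tf.t2, tf.t3, tf.t4
    n, p = tf.n_subjects, tf.p
    if target == "spherical":
        num = t3 + t2
        den = n * t2 + ((p - n + 1) / p) * t3
    elif target == "identity":
        num = t3 + t2
        den = n * (t2 - 2 * t1 + p) + t2 + t3
    elif target == "diagonal":
        num = t3 + t2 - 2 * t4
        den = n * (t2 - t4) + t2 + t3 - 2 * t4
    else:
        raise ValueError(f"unknown target {target!r}")
    if den <= 0:
        warnings.warn(
            f"nonpositive intensity denominator for target {target!r}; data are "
            "degenerate or already inside the target family, using lambda = 1",
            stacklevel=2,
        )
        return 1.0
    return float(min(1.0, max(0.0, num / den)))


def shrink_covariance(ds: TransposableDataset, side: str, target: str) -> CovarianceEstimate:
    """Stein-type shrinkage estimate of Sigma_R or Sigma_C.

    Requires N >= 4 (the intensity uses distinct-quadruple U-statistics).
    Column output is renormalized to trace c after mixing.
    """
    est = sample_covariance(ds, side)
    tf = trace_functionals(ds, side)
    lam = shrinkage_intensity(tf, target)
    p = tf.p
    if target == "spherical":
        t = (tf.t1 / p) * np.eye(p)
    elif target == "identity":
        t = np.eye(p)
    else:
        t = np.diag(np.diag(est.matrix))
    m = (1.0 - lam) * est.matrix + lam * t
    if side == "columns":
        m = m * (p / np.trace(m))
    return CovarianceEstimate(side, m, target, lam, _normalization_note(side), est.ids)


def correlation_from_covariance(est: CovarianceEstimate) -> tuple[pd.Series, pd.DataFrame]:
    """Split a covariance estimate into standard deviations and a unit-diagonal
    correlation matrix (both labelled)."""
    diag = np.diag(est.matrix)
    bad = np.flatnonzero(diag <= 0)
    if bad.size:
        raise ValueError(
            f"nonpositive variance for label {est.ids[bad[0]]!r}: cannot form correlations"
        )
    sd = np.sqrt(diag)
    corr = est.matrix / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return (
        pd.Series(sd, index=est.ids, name="sd"),
        pd.DataFrame(corr, index=est.ids, columns=est.ids),
    )
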