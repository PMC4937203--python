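"""Sphericity and identity tests for the row or column covariance matrix.

Both tests are built from the trace functionals of
:mod:`kronstat.traces`:

* sphericity (H0: Sigma proportional to I, i.e. equal variances and zero
  correlations): U = p * t2 / t1^2 - 1, a scale-free distance with
  population value tr(Sigma^2) tr^{-2}(Sigma) * p - 1 = 0 iff Sigma ~ I;
* identity (H0: Sigma = I under the tr(Sigma_C) = c convention):
  V = (t2 - 2 t1 + p) / p, the population value ||Sigma - I||_F^2 / p.

Standardization.  Under H0 the dominant fluctuation of either statistic
comes from the quadruple U-statistic t2 through the kernel
phi(G_i, G_k) = p tr(G_i G_k) - tr(G_i) tr(G_k) of the per-subject Grams,
whose second moments are governed by the *other* side's covariance.  A
Hoeffding-projection calculation under Gaussian sampling shows that, as
the non-tested dimension grows, the second-order projection dominates and
the null law of U is a centered, scaled chi-square:

    N p U / (2 rho_o)  ->  chi2_nu - nu,   nu = (p - 1)(p + 2) / 2,

where rho_o = tr(Sigma_other^2) / tr^2(Sigma_other) is a scale-free
nuisance ratio (the same limit as the classical John sphericity statistic,
with the effective sample scale set by N and rho_o).  P-values use this
chi-square reference — which captures the right skew of the null for small
tested dimension p — and the reported z is the equivalent normal quantile,
so p = 1 - Phi(z) still holds.  The same standardization is applied to V.
rho_o is estimated from the same data: testing
rows it is the column ratio t2_C / c^2; testing columns it is the
vectorized-sample ratio tr(Omega^2)/tr^2(Omega) (Omega = Sigma_C (x)
Sigma_R, estimated from the centered subject Gram) divided by the column
ratio.  The standardization constant was verified against the simulated
null spread of U and is exercised by the size-calibration simulations in
the test suite; a Monte-Carlo p-value mode (``pvalue="mc"``) is available
as a distribution-free fallback.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import chi2, norm

from ._pairs import disjoint_product_mean, pair_indices
from .data import TransposableDataset, subset as subset_ds
from .mean_tests import TestResult, bh_adjust
from .traces import trace_functionals

__all__ = [
    "sphericity_statistic",
    "identity_statistic",
    "sphericity_test",
    "identity_test",
    "all_pairs_sphericity",
]

_RATIO_FLOOR = 1e-12


def sphericity_statistic(t1: float, t2: float, p: int) -> float:
    """Scale-free sphericity distance U = p t2/t1^2 - 1 (0 iff Sigma ~ I)."""
    return p * t2 / t1**2 - 1.0


def identity_statistic(t1: float, t2: float, p: int) -> float:
    """Identity distance V = (t2 - 2 t1 + p)/p, i.e. ||Sigma - I||_F^2 / p."""
    return (t2 - 2.0 * t1 + p) / p


def _vec_gram_ratio(x: np.ndarray) -> float:
    """Estimate tr(Omega^2)/tr^2(Omega) of the vectorized covariance from
    the centered subject Gram matrix (Gaussian-unbiased numerator)."""
    n_sub = x.shape[0]
    v = x.reshape(n_sub, -1)
    v = v - v.mean(axis=0)
    g = v @ v.T
    n = n_sub - 1
    tr_s = np.trace(g) / n
    tr_s2 = float((g * g).sum()) / n**2
    a2 = (n**2 / ((n - 1) * (n + 2))) * (tr_s2 - tr_s**2 / n)
    if tr_s <= 0:
        raise ValueError("degenerate data: zero total variance")
    return max(a2 / tr_s**2, _RATIO_FLOOR)


def _nuisance_ratio(sub: TransposableDataset, side: str, col_ratio: float) -> float:
    """Scale-free ratio tr(Sigma_o^2)/tr^2(Sigma_o) of the non-tested side."""
    if side == "rows":
        return max(col_ratio, _RATIO_FLOOR)
    return max(_vec_gram_ratio(sub.values) / max(col_ratio, _RATIO_FLOOR), _RATIO_FLOOR)


def _reference_pvalue(stat: float, n: int, p: int, nuisance: float) -> tuple[float, float]:
    """(z, p-value) from the centered chi-square null reference.

    N p stat / (2 rho_o) is compared with chi2_nu - nu, nu = (p-1)(p+2)/2;
    z is the equivalent standard-normal quantile of the p-value.
    """
    nu = (p - 1) * (p + 2) / 2.0
    x = n * p * stat / (2.0 * nuisance)
    pv = float(chi2.sf(x + nu, nu))
    z = float(norm.isf(min(max(pv, 1e-300), 1.0 - 1e-16)))
    return z, pv


def _subsetted(ds: TransposableDataset, side: str, subset) -> TransposableDataset:
    if side not in ("rows", "columns"):
        raise ValueError(f"side must be 'rows' or 'columns', got {side!r}")
    if subset is None:
        return ds
    return subset_ds(ds, rows=subset) if side == "rows" else subset_ds(ds, cols=subset)


def _mc_pvalue(
    sub: TransposableDataset, side: str, stat_fn, observed: float, n_reps: int, seed: int
) -> float:
    """Monte-Carlo p-value: simulate the Gaussian null with the tested side
    spherical/identity and the other side set to its spherical-target
    shrinkage estimate; p = (1 + #{U* >= U}) / (R + 1)."""
    from .shrinkage import shrink_covariance
    from .simulate import SimulationConfig, sample_dataset

    n, r, c = sub.values.shape
    other = "columns" if side == "rows" else "rows"
    sigma_o = shrink_covariance(sub, other, "spherical").matrix
    tf = trace_functionals(sub, side)
    scale = tf.t1 / tf.p
    if side == "rows":
        sigma_r, sigma_c = scale * np.eye(r), sigma_o
    else:
        sigma_r, sigma_c = sigma_o, scale * np.eye(c)
    hits = 0
    base = np.random.SeedSequence(int(seed)).generate_state(n_reps)
    for s in base:
        cfg = SimulationConfig(
            np.zeros((r, c)), sigma_r, sigma_c, n, seed=int(s % (2**31 - 1))
        )
        null = sample_dataset(cfg)
        tf0 = trace_functionals(null, side)
        hits += stat_fn(tf0.t1, tf0.t2, tf0.p) >= observed
    return (1 + hits) / (n_reps + 1)


def _cov_test(
    ds: TransposableDataset,
    side: str,
    subset,
    stat_fn,
    hypothesis: str,
    pvalue: str,
    n_reps: int,
    seed: int,
) -> TestResult:
    sub = _subsetted(ds, side, subset)
    tf = trace_functionals(sub, side)
    if tf.p < 2:
        raise ValueError("covariance tests need dimension p >= 2")
    stat = stat_fn(tf.t1, tf.t2, tf.p)
    col_tf = tf if side == "columns" else trace_functionals(sub, "columns")
    col_ratio = col_tf.t2 / col_tf.p**2
    nuis = _nuisance_ratio(sub, side, col_ratio)
    z, pv = _reference_pvalue(stat, tf.n_subjects, tf.p, nuis)
    if pvalue == "mc":
        pv = _mc_pvalue(sub, side, stat_fn, stat, n_reps, seed)
        z = float(norm.isf(min(max(pv, 1e-300), 1.0 - 1e-16)))
    elif pvalue != "analytic":
        raise ValueError(f"unknown pvalue mode {pvalue!r}")
    labels = sub.row_ids if side == "rows" else sub.col_ids
    return TestResult(
        statistic=float(stat),
        z=float(z),
        p_value=pv,
        hypothesis=hypothesis.format(side=side, labels=",".join(labels)),
        details={
            "side": side,
            "labels": list(labels),
            "p": tf.p,
            "n_subjects": tf.n_subjects,
            "t1": tf.t1,
            "t2": tf.t2,
            "nuisance_ratio": nuis,
            "normalization": "tr(Sigma_C)=c",
            "pvalue_mode": pvalue,
        },
    )


def sphericity_test(
    ds: TransposableDataset,
    side: str = "columns",
    subset=None,
    pvalue: str = "analytic",
    n_reps: int = 200,
    seed: int = 0,
) -> TestResult:
    """Test H0: Sigma_{side} is *proportional to the identity* on the given
    label subset (for a column pair: equal variances and zero correlation).

    One-sided: large U (hence large z) rejects.  ``pvalue="mc"`` replaces
    the normal reference by a parametric-bootstrap null.
    """
    return _cov_test(
        ds,
        side,
        subset,
        sphericity_statistic,
        "Sigma_{side} proportional to identity on [{labels}]",
        pvalue,
        n_reps,
        seed,
    )


def identity_test(
    ds: TransposableDataset,
    side: str = "rows",
    subset=None,
    pvalue: str = "analytic",
    n_reps: int = 200,
    seed: int = 0,
) -> TestResult:
    """Test H0: Sigma_{side} = I on the given label subset, under the
    tr(Sigma_C) = c identifiability convention (on the column side this
    coincides with sphericity, since the scale is fixed)."""
    return _cov_test(
        ds,
        side,
        subset,
        identity_statistic,
        "Sigma_{side} equal to identity on [{labels}] (tr(Sigma_C)=c convention)",
        pvalue,
        n_reps,
        seed,
    )


def all_pairs_sphericity(
    ds: TransposableDataset, side: str = "columns", fdr: float = 0.05
) -> tuple[list[TestResult], np.ndarray]:
    """Sphericity tests for every unordered column pair, BH-adjusted.

    Produces exactly the same per-pair statistics as calling
    :func:`sphericity_test` on each two-column subset, but shares the pair
    differences and per-column Grams across the C(c,2) tests so whole-panel
    screens stay cheap.  Each result's ``details`` carries the pair, the
    adjusted p-value and whether it is rejected at the requested FDR.
    """
    if side != "columns":
        raise ValueError("all-pairs screening is defined for side='columns'")
    x = ds.values
    n, r, c = x.shape
    if c < 2:
        raise ValueError("need at least two columns")
    if n < 4:
        raise ValueError("insufficient subjects for quadruple U-statistics (need N >= 4)")
    I, J = pair_indices(n)
    d = (x[I] - x[J]) / math.sqrt(2.0)
    w = np.einsum("prc,prd->pcd", d, d)  # per-pair column Grams
    # quadruple means of entrywise products, shared across pairs
    m_diag = np.empty((c, c))  # avg_disjoint W_p[a,a] W_q[b,b]
    for a in range(c):
        for b in range(a, c):
            m_diag[a, b] = m_diag[b, a] = disjoint_product_mean(w[:, a, a], w[:, b, b], I, J, n)
    m_off = np.empty((c, c))  # avg_disjoint W_p[a,b] W_q[a,b]
    for a in range(c):
        for b in range(a + 1, c):
            m_off[a, b] = m_off[b, a] = disjoint_product_mean(w[:, a, b], w[:, a, b], I, J, n)
    gcol = np.einsum("aru,bru->abu", x, x)  # per-column subject inner products
    results = []
    for u in range(c):
        for v in range(u + 1, c):
            q2 = m_diag[u, u] + m_diag[v, v] + 2.0 * m_off[u, v]
            q3 = m_diag[u, u] + m_diag[v, v] + 2.0 * m_diag[u, v]
            stat = 2.0 * q2 / q3 - 1.0
            col_ratio = q2 / q3
            gm = gcol[:, :, u] + gcol[:, :, v]
            gm = gm - gm.mean(axis=0, keepdims=True)
            gm = gm - gm.mean(axis=1, keepdims=True)
            nn = n - 1
            tr_s = np.trace(gm) / nn
            tr_s2 = float((gm * gm).sum()) / nn**2
            a2 = (nn**2 / ((nn - 1) * (nn + 2))) * (tr_s2 - tr_s**2 / nn)
            ratio_omega = max(a2 / tr_s**2, _RATIO_FLOOR) if tr_s > 0 else _RATIO_FLOOR
            nuis = max(ratio_omega / max(col_ratio, _RATIO_FLOOR), _RATIO_FLOOR)
            z, pv = _reference_pvalue(stat, n, 2, nuis)
            pair = (ds.col_ids[u], ds.col_ids[v])
            results.append(
                TestResult(
                    statistic=float(stat),
                    z=float(z),
                    p_value=pv,
                    hypothesis=f"Sigma_columns proportional to identity on [{pair[0]},{pair[1]}]",
                    details={
                        "side": "columns",
                        "labels": list(pair),
                        "p": 2,
                        "n_subjects": n,
                        "nuisance_ratio": nuis,
                        "normalization": "tr(Sigma_C)=c",
                        "pvalue_mode": "analytic",
                    },
                )
            )
    adj = bh_adjust([t.p_value for t in results])
    for res, a in zip(results, adj):
        res.details["p_adj"] = float(a)
        res.details["reject_fdr"] = bool(a < fdr)
        res.details["fdr_level"] = fdr
    return results, adj
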