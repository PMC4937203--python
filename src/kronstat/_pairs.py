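"""Index bookkeeping for pair-difference U-statistics.

The estimators in :mod:`kronstat.traces` average kernels over *distinct
quadruples* of subjects (i, j, k, l).  Because every kernel is symmetric
within and across the two pair slots, such an average equals the average
over ordered pairs (p, q) of subject pairs p = {i, j}, q = {k, l} that
share no subject.  These helpers build the pair index arrays, the
disjointness mask, and fast masked means.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = [
    "pair_indices",
    "disjoint_pair_mask",
    "disjoint_pair_count",
    "masked_quad_mean",
    "disjoint_feature_sum",
    "disjoint_product_mean",
]


@lru_cache(maxsize=32)
def pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Arrays (I, J) with I[p] < J[p] enumerating all n(n-1)/2 subject pairs."""
    iu = np.triu_indices(n, k=1)
    return iu[0].astype(np.intp), iu[1].astype(np.intp)


@lru_cache(maxsize=8)
def _disjoint_pair_mask_for(n: int) -> np.ndarray:
    I, J = pair_indices(n)
    share = (
        (I[:, None] == I[None, :])
        | (I[:, None] == J[None, :])
        | (J[:, None] == I[None, :])
        | (J[:, None] == J[None, :])
    )
    return ~share


def disjoint_pair_mask(I: np.ndarray, J: np.ndarray) -> np.ndarray:
    """Boolean (P, P) mask, True where pairs p and q share no subject.

    For the canonical i<j enumeration the mask depends only on N, so it is
    cached across calls.
    """
    n = int(J.max()) + 1 if len(J) else 0
    canon_i, canon_j = pair_indices(n)
    if len(canon_i) == len(I) and np.array_equal(canon_i, I) and np.array_equal(canon_j, J):
        return _disjoint_pair_mask_for(n)
    share = (
        (I[:, None] == I[None, :])
        | (I[:, None] == J[None, :])
        | (J[:, None] == I[None, :])
        | (J[:, None] == J[None, :])
    )
    return ~share


def disjoint_pair_count(n: int) -> int:
    """Number of ordered disjoint pair-pairs: 3 * n(n-1)(n-2)(n-3)/8... computed
    exactly as P^2 - n(n-1)^2 + P with P = n(n-1)/2."""
    p = n * (n - 1) // 2
    return p * p - n * (n - 1) ** 2 + p


def masked_quad_mean(kernel: np.ndarray, mask: np.ndarray) -> float:
    """Mean of kernel[p, q] over ordered disjoint (p, q)."""
    cnt = int(mask.sum())
    if cnt == 0:
        raise ValueError("no disjoint subject quadruples (need N >= 4)")
    return float(kernel[mask].sum() / cnt)


@lru_cache(maxsize=8)
def _incidence(n: int) -> np.ndarray:
    """(N, P) 0/1 matrix: subject s belongs to pair p."""
    I, J = pair_indices(n)
    m = np.zeros((n, len(I)))
    m[I, np.arange(len(I))] = 1.0
    m[J, np.arange(len(J))] = 1.0
    return m


def disjoint_feature_sum(features: np.ndarray, n: int) -> float:
    """Sum of <F_p, F_q> over ordered disjoint pair-pairs, in O(P) space.

    ``features`` has shape (P, ...) in canonical i<j pair order; the kernel
    is the Euclidean inner product of the flattened feature vectors.  Uses
    sum_disjoint <F_p, F_q> = ||sum_p F_p||^2 - sum_s ||T_s||^2
    + sum_p ||F_p||^2 with T_s the feature total over pairs containing
    subject s.
    """
    f = features.reshape(features.shape[0], -1)
    tot = f.sum(axis=0)
    ts = _incidence(n) @ f
    return float(tot @ tot - (ts * ts).sum() + (f * f).sum())


def disjoint_product_mean(
    u: np.ndarray, v: np.ndarray, I: np.ndarray, J: np.ndarray, n: int
) -> float:
    """Mean of u[p] * v[q] over ordered disjoint pair-pairs in O(P) time.

    Uses the identity
    sum_disjoint u_p v_q = (sum u)(sum v) - sum_s T_s(u) T_s(v) + sum_p u_p v_p,
    where T_s(u) is the total of u over pairs containing subject s; the
    middle term removes pair-pairs sharing at least one subject, the last
    corrects for p = q being removed twice.
    """
    cnt = disjoint_pair_count(n)
    if cnt == 0:
        raise ValueError("no disjoint subject quadruples (need N >= 4)")
    tu = np.bincount(I, weights=u, minlength=n) + np.bincount(J, weights=u, minlength=n)
    tv = np.bincount(I, weights=v, minlength=n) + np.bincount(J, weights=v, minlength=n)
    total = u.sum() * v.sum() - tu @ tv + u @ v
    return float(total / cnt)
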