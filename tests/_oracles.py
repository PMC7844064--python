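"""Independent oracles used by the test suite.

Each oracle computes the checked quantity by a route disjoint from the
implementation: exhaustive vertex enumeration for the transportation LP,
plain dictionary recounting for the cluster filter, a closed-form normal
z-test for the score comparison.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy import stats


@lru_cache(maxsize=8)
def _transport_bases(n: int, m: int):
    """All candidate basic solutions of the (n, m) transportation polytope.

    The constraint matrix (n row sums + m column sums, last row dropped as
    redundant) has rank n+m−1; every vertex is A_S^{-1} b for some column
    subset S of that size.  Returns the subsets' cost-index lists and the
    pseudo-inverses of the corresponding submatrices, precomputed once per
    shape since A depends only on (n, m).
    """
    A = np.zeros((n + m, n * m))
    for idx in range(n * m):
        i, j = divmod(idx, m)
        A[i, idx] = 1.0
        A[n + j, idx] = 1.0
    A = A[:-1]
    k = n + m - 1
    subsets = np.array(list(combinations(range(n * m), k)))
    mats = A[:, subsets].transpose(1, 0, 2)  # (n_sub, k, k)
    pinvs = np.linalg.pinv(mats)
    return A, subsets, mats, pinvs


def emd_bruteforce(p: np.ndarray, q: np.ndarray, D: np.ndarray) -> float:
    """Exact EMD by enumerating every vertex of the transportation polytope."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    n, m = len(p), len(q)
    A, subsets, mats, pinvs = _transport_bases(n, m)
    b = np.concatenate([p, q])[:-1]
    x = pinvs @ b                                   # (n_sub, k)
    residual = np.abs(mats @ x[..., None] - b[:, None]).max(axis=(1, 2))
    feasible = (residual < 1e-9) & (x.min(axis=1) > -1e-9)
    if not feasible.any():
        raise AssertionError("no feasible transportation vertex found")
    costs = np.take(D.ravel(), subsets[feasible])   # cost coefficients
    values = (costs * np.clip(x[feasible], 0.0, None)).sum(axis=1)
    return float(values.min())


def filter_recount(labels, compound_ids, min_count):
    """Brute-force recount of the strictly-more-than filter: returns the set
    of retained original cluster labels."""
    counts: dict[tuple[int, str], int] = {}
    for lab, cid in zip(labels, compound_ids):
        counts[(lab, cid)] = counts.get((lab, cid), 0) + 1
    return {lab for (lab, _), c in counts.items() if c > min_count}


def welch_z_oracle(a, b):
    """Closed-form normal approximation of the two-sample mean comparison."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    z = (a.mean() - b.mean()) / se
    return z, 2.0 * stats.norm.sf(abs(z))
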