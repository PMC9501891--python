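"""Rank-based two-sample testing and multiple-testing helpers.

The exact two-sided Wilcoxon rank-sum p-value is defined by full enumeration
of the permutation distribution of the rank sum: with no ties, the null
distribution of W (sum of group-a ranks) is computed by dynamic programming
over subsets of ranks 1..N, and the p-value is the probability of a rank sum
at least as far from its null mean as observed.  For tied data or N > 20 a
normal approximation with tie and continuity correction is used.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import stats as sps

__all__ = ["wilcoxon_rank_sum", "bh_fdr"]


@lru_cache(maxsize=64)
def _ranksum_counts(n_a: int, n_total: int) -> tuple:
    """Number of size-n_a subsets of ranks 1..n_total attaining each rank sum.

    Returns a tuple indexed by rank sum (0..n_a*n_total); standard subset-sum
    dynamic programme, O(n_total^2 * n_a) time.
    """
    max_sum = n_a * n_total
    counts = np.zeros((n_a + 1, max_sum + 1), dtype=np.int64)
    counts[0, 0] = 1
    for r in range(1, n_total + 1):
        kmax = min(n_a, r)
        for k in range(kmax, 0, -1):
            counts[k, r:] += counts[k - 1, : max_sum + 1 - r]
    return tuple(counts[n_a].tolist())


def _exact_two_sided_p(w: float, n_a: int, n_b: int) -> float:
    n = n_a + n_b
    counts = np.array(_ranksum_counts(n_a, n), dtype=float)
    total = counts.sum()
    mean = n_a * (n + 1) / 2.0
    sums = np.arange(counts.size, dtype=float)
    dev = abs(w - mean)
    # tiny slack guards float comparison of half-integer deviations
    p = counts[np.abs(sums - mean) >= dev - 1e-9].sum() / total
    return float(min(p, 1.0))


def wilcoxon_rank_sum(group_a, group_b, method: str = "auto"):
    """Two-sided Wilcoxon rank-sum test.

    Parameters
    ----------
    group_a, group_b
        Nonempty samples of real values.
    method
        ``exact`` — full enumeration of the rank-sum null (requires no ties
        and n_a + n_b <= 20); ``normal`` — large-sample approximation with
        tie correction and continuity correction; ``auto`` (default) picks
        ``exact`` when admissible.

    Returns
    -------
    (W, p)
        W is the rank sum of ``group_a`` (midranks for ties); p is the
        two-sided p-value in (0, 1].
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n_a].sum())
    has_ties = np.unique(pooled).size < n

    if method not in {"exact", "normal", "auto"}:
        raise ValueError(f"unknown method {method!r}")
    if method == "exact":
        if has_ties:
            raise ValueError("exact method requires untied data")
        if n > 20:
            raise ValueError("exact method requires n_a + n_b <= 20")
    if method == "auto":
        method = "exact" if (not has_ties and n <= 20) else "normal"

    if method == "exact":
        return w, _exact_two_sided_p(w, n_a, n_b)

    mean = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all observations identical
        return w, 1.0
    dev = abs(w - mean)
    z = max(dev - 0.5, 0.0) / np.sqrt(var)  # continuity-corrected
    p = 2.0 * sps.norm.sf(z)
    return w, float(min(p, 1.0))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-aligned with the input.

    q_(i) = min_{j >= i} (m * p_(j) / j), clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
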