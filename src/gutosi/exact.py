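"""Exact small-sample null distributions by enumeration.

scipy provides exact p-values for the Wilcoxon rank-sum test but not for
the Kruskal-Wallis H statistic or for Spearman correlation under the
permutation null.  These are needed at the study's group sizes (9 + 9 and
smaller), where chi-square / t approximations are visibly off, so the
enumeration is done here.  Null distributions depend only on the pooled
rank multiset and the group sizes, so they are cached and shared across
features.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations, permutations
from math import comb, factorial

import numpy as np
from scipy.stats import rankdata

#: largest number of multiset permutations enumerated before falling back
#: to the chi-square approximation
KW_EXACT_LIMIT = 200_000

#: largest n for which Spearman permutation p-values are enumerated (n! perms)
SPEARMAN_EXACT_LIMIT = 8


def kw_statistic(ranks: np.ndarray, sizes: tuple[int, ...], tie_term: float) -> float:
    """Kruskal-Wallis H from pooled ranks laid out group-by-group."""
    n = ranks.shape[0]
    h = 0.0
    start = 0
    for size in sizes:
        rsum = ranks[start : start + size].sum()
        h += rsum * rsum / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    if tie_term > 0:
        h /= tie_term
    return h


def _tie_correction(ranks: np.ndarray) -> float:
    n = ranks.shape[0]
    _, counts = np.unique(ranks, return_counts=True)
    return 1.0 - float(((counts**3 - counts).sum()) / (n**3 - n))


def n_multiset_assignments(sizes: tuple[int, ...]) -> int:
    n = sum(sizes)
    total = 1
    rem = n
    for size in sizes:
        total *= comb(rem, size)
        rem -= size
    return total


@lru_cache(maxsize=64)
def _kw_null_distribution(sizes: tuple[int, ...], ranks_key: tuple[float, ...]) -> np.ndarray:
    """All values of H over multiset assignments of the pooled ranks.

    Two-group assignments are enumerated vectorized (the 9 + 9 design has
    48620); k-group assignments recurse over per-group rank sums.
    """
    ranks = np.array(ranks_key, dtype=float)
    tie = _tie_correction(ranks)
    n = len(ranks)
    if len(sizes) == 2:
        combos = np.array(list(combinations(range(n), sizes[0])), dtype=np.intp)
        r1 = ranks[combos].sum(axis=1)
        r2 = ranks.sum() - r1
        h = 12.0 / (n * (n + 1)) * (r1**2 / sizes[0] + r2**2 / sizes[1]) - 3.0 * (n + 1)
    else:
        rank_sums: list[list[float]] = []

        def recurse(remaining: np.ndarray, sums: list[float]) -> None:
            if len(sums) == len(sizes) - 1:
                rank_sums.append(sums + [float(ranks[remaining].sum())])
                return
            size = sizes[len(sums)]
            for combo in combinations(range(len(remaining)), size):
                sel = remaining[list(combo)]
                mask = np.ones(len(remaining), dtype=bool)
                mask[list(combo)] = False
                recurse(remaining[mask], sums + [float(ranks[sel].sum())])

        recurse(np.arange(n), [])
        sums_arr = np.asarray(rank_sums)
        h = (12.0 / (n * (n + 1))
             * (sums_arr**2 / np.asarray(sizes, dtype=float)).sum(axis=1)
             - 3.0 * (n + 1))
    if tie > 0:
        h = h / tie
    return np.sort(h)


def kruskal_exact(groups: list[np.ndarray]) -> tuple[float, float]:
    """Exact Kruskal-Wallis test by enumeration.

    Returns (H, p) where p = P(H_perm >= H_obs) over all assignments of
    the pooled (possibly tied) ranks to groups of the observed sizes.
    Falls back on the caller to check :func:`n_multiset_assignments`
    against :data:`KW_EXACT_LIMIT`.
    """
    sizes = tuple(len(g) for g in groups)
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = rankdata(pooled)
    tie = _tie_correction(ranks)
    if tie <= 0:  # every observation identical
        return 0.0, 1.0
    h_obs = kw_statistic(ranks, sizes, tie)
    null = _kw_null_distribution(sizes, tuple(np.sort(ranks)))
    # enumeration over sorted ranks covers the same multiset; null is sorted
    p = 1.0 - np.searchsorted(null, h_obs - 1e-12, side="left") / null.shape[0]
    return float(h_obs), float(p)


@lru_cache(maxsize=32)
def _spearman_null_distribution(y_ranks_key: tuple[float, ...], x_ranks_key: tuple[float, ...]) -> np.ndarray:
    """|rho| over all permutations of x-ranks against fixed y-ranks."""
    y = np.array(y_ranks_key, dtype=float)
    x = np.array(x_ranks_key, dtype=float)
    n = len(y)
    ycen = y - y.mean()
    ynorm = np.sqrt((ycen**2).sum())
    perms = np.array(list(permutations(x)), dtype=float)
    xcen = perms - perms.mean(axis=1, keepdims=True)
    xnorm = np.sqrt((xcen**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (xcen @ ycen) / (xnorm * ynorm)
    return np.abs(rho)


def spearman_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with a two-sided exact permutation p-value.

    Enumerates all n! orderings of x's ranks (n <= SPEARMAN_EXACT_LIMIT);
    p = P(|rho_perm| >= |rho_obs|).  Degenerate (constant) inputs return
    rho = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("length mismatch")
    if factorial(n) > factorial(SPEARMAN_EXACT_LIMIT):
        raise ValueError(f"exact Spearman limited to n <= {SPEARMAN_EXACT_LIMIT}")
    rx = rankdata(x)
    ry = rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return 0.0, 1.0
    rho_obs = float(np.corrcoef(rx, ry)[0, 1])
    null = _spearman_null_distribution(tuple(ry), tuple(np.sort(rx)))
    p = float(np.mean(null >= abs(rho_obs) - 1e-12))
    return rho_obs, p
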