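"""Independent brute-force oracles used to check the fast implementations.

Everything here is written from the definitions alone (direct counting,
exhaustive enumeration, textbook formulas) and never calls the package's
own code paths.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def loading_p_oracle(
    loadings: np.ndarray, pc: int, transcript: int, exclude_self: bool = True
) -> tuple[float, int]:
    """Empirical loading P value by direct counting.

    ``pc`` is a 0-based column index. Returns (p, null_size); L = 0 gives
    (1.0, 0) and an empty same-sign null gives (0.0, 0).
    """
    L = float(loadings[transcript, pc])
    null = []
    for t in range(loadings.shape[0]):
        if exclude_self and t == transcript:
            continue
        for k in range(loadings.shape[1]):
            if k == pc:
                continue
            null.append(float(loadings[t, k]))
    if L == 0.0:
        return 1.0, 0
    if L > 0:
        same = [v for v in null if v > 0]
        exceed = [v for v in null if v > L]
    else:
        same = [v for v in null if v < 0]
        exceed = [v for v in null if v < L]
    if not same:
        return 0.0, 0
    return len(exceed) / len(same), len(same)


def loading_p_oracle_matrix(
    loadings: np.ndarray, pc: int, exclude_self: bool = True
) -> np.ndarray:
    """Empirical loading P values for every transcript by direct counting.

    Same definition as :func:`loading_p_oracle` but formulated with plain
    boolean reductions per transcript so larger matrices stay tractable.
    """
    others = np.delete(loadings, pc, axis=1)
    out = np.empty(loadings.shape[0])
    for t in range(loadings.shape[0]):
        L = loadings[t, pc]
        null = np.delete(others, t, axis=0).ravel() if exclude_self else others.ravel()
        if L == 0.0:
            out[t] = 1.0
        elif L > 0:
            denom = int((null > 0).sum())
            out[t] = (null > L).sum() / denom if denom else 0.0
        else:
            denom = int((null < 0).sum())
            out[t] = (null < L).sum() / denom if denom else 0.0
    return out


def hypergeom_upper_tail_enum(M: int, K: int, N: int, k: int) -> float:
    """P(X >= k) by exhaustive enumeration of all N-subsets of a universe
    of size M containing K successes. Only feasible for small M."""
    universe = list(range(M))
    successes = set(universe[:K])
    hits = total = 0
    for draw in combinations(universe, N):
        total += 1
        if len(successes.intersection(draw)) >= k:
            hits += 1
    return hits / total


def hypergeom_upper_tail_formula(M: int, K: int, N: int, k: int) -> float:
    """P(X >= k) from the closed-form hypergeometric sum."""
    denom = comb(M, N)
    num = sum(
        comb(K, i) * comb(M - K, N - i)
        for i in range(max(k, 0), min(K, N) + 1)
        if N - i <= M - K
    )
    return num / denom


def bh_step_up(p: np.ndarray) -> np.ndarray:
    """Textbook BH: adj_(i) = min_{j >= i} min(1, m * p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.minimum(1.0, p[order] * m / np.arange(1, m + 1))
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def anova_f_oracle(groups: list[np.ndarray]) -> float:
    """One-way ANOVA F from the definition (sum-of-squares arithmetic)."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    k = len(groups)
    N = len(all_vals)
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return (ssb / (k - 1)) / (ssw / (N - k))
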