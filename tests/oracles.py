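"""Independent brute-force oracles used across the test suite.

These deliberately avoid the code paths they check: combinatorial
enumeration with ``math.comb``, exhaustive permutation loops via
``itertools``, and plain pairwise loops for neighbor search.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats


def hypergeom_tail(n_obs: int, n_total: int, n_success: int, k_draws: int) -> float:
    """P(H >= n_obs) by direct summation of the hypergeometric pmf."""
    total = 0
    for i in range(n_obs, k_draws + 1):
        if i > n_success or k_draws - i > n_total - n_success:
            continue
        total += math.comb(n_success, i) * math.comb(n_total - n_success, k_draws - i)
    return total / math.comb(n_total, k_draws)


def knn_bruteforce(points: np.ndarray, k: int) -> np.ndarray:
    """All-pairs distance sort with explicit loops; ties by ascending index."""
    n = len(points)
    out = np.empty((n, k), dtype=int)
    for i in range(n):
        dists = []
        for j in range(n):
            if j == i:
                continue
            dists.append((float(np.sqrt(((points[i] - points[j]) ** 2).sum())), j))
        dists.sort()
        out[i] = [j for _, j in dists[:k]]
    return out


def spearman_exact_p(fractions: np.ndarray, variable: np.ndarray) -> tuple[float, float]:
    """(rho, two-sided exact permutation p) by looping over all orderings."""
    rho_obs = stats.spearmanr(fractions, variable).statistic
    if np.isnan(rho_obs):
        return 0.0, 1.0
    count = 0
    total = 0
    for perm in itertools.permutations(variable):
        r = stats.spearmanr(fractions, perm).statistic
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return float(rho_obs), count / total


def top_set_overlap_p(n_genes: int, top: set, pathway: set, universe: list) -> float:
    """P(overlap >= observed) by enumerating every possible top set."""
    t = len(top)
    obs = len(top & pathway)
    hits = 0
    total = 0
    for combo in itertools.combinations(universe, t):
        total += 1
        if len(set(combo) & pathway) >= obs:
            hits += 1
    return hits / total


def aroc_pair_count(scores: np.ndarray, truth: np.ndarray) -> float:
    """Concordant-pair fraction with ties counted half."""
    pos = scores[truth.astype(bool)]
    neg = scores[~truth.astype(bool)]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def welch_t_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-tailed Welch t-test from the textbook formulas."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return float(2 * stats.t.sf(abs(t), df))
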