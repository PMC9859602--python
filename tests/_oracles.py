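"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package: the aligner enumerates
all substring pairs with a plain global DP, and the signed-rank test
enumerates all 2^n sign assignments.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from scipy.stats import rankdata

NEG = float("-inf")


def global_affine_score(a: str, b: str, match=1, mismatch=-1, gap_open=-4, gap_extend=-1):
    """Global alignment score of two (short) strings, affine gaps costing
    gap_open for the first gapped position and gap_extend thereafter."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (b consumed)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                s = match if a[i - 1] == b[j - 1] else mismatch
                M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            if i > 0:
                best = max(M[i - 1][j], Y[i - 1][j])
                X[i][j] = max(best + gap_open, X[i - 1][j] + gap_extend)
            if j > 0:
                best = max(M[i][j - 1], X[i][j - 1])
                Y[i][j] = max(best + gap_open, Y[i][j - 1] + gap_extend)
    return max(M[n][m], X[n][m], Y[n][m])


def brute_force_local_score(a: str, b: str, **scores) -> float:
    """Best local alignment score by exhausting all substring pairs (O(n^2 m^2)
    DP evaluations); the empty alignment scores 0."""
    best = 0.0
    for i1, i2 in itertools.combinations(range(len(a) + 1), 2):
        for j1, j2 in itertools.combinations(range(len(b) + 1), 2):
            s = global_affine_score(a[i1:i2], b[j1:j2], **scores)
            if s > best:
                best = s
    return best


def wilcoxon_enumeration(x, y) -> float:
    """Exact two-sided signed-rank p-value by enumerating all 2^n sign
    assignments of the |difference| ranks (average ranks for ties)."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = []
    for signs in itertools.product([0, 1], repeat=n):
        w_all.append(sum(r for r, s in zip(ranks, signs) if s))
    w_all = np.array(w_all)
    n_total = w_all.size
    p_le = (w_all <= w_obs + 1e-12).sum() / n_total
    p_ge = (w_all >= w_obs - 1e-12).sum() / n_total
    return min(1.0, 2.0 * min(p_le, p_ge))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
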