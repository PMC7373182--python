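"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the code paths (and libraries) used by the
package: alignments are scored by enumerating all substring pairs with a
memoized global recursion, BH by the literal step-up definition, and
hypergeometric tails by combinatorial sums.
"""

from __future__ import annotations

import math
from functools import lru_cache

NEG = float("-inf")


def best_local_alignment_score(
    x: str,
    y: str,
    pair_score,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Best local alignment score by enumerating all substring pairs.

    Each substring pair is aligned globally with affine gaps (first gapped
    position costs ``gap_open``, each further one ``gap_extend``); the local
    optimum is the maximum over all pairs, floored at 0 (empty alignment).
    """

    def global_best(xs: str, ys: str) -> float:
        @lru_cache(maxsize=None)
        def go(i: int, j: int, last: str) -> float:
            if i == len(xs) and j == len(ys):
                return 0.0
            best = NEG
            if i < len(xs) and j < len(ys):
                best = max(best, pair_score(xs[i], ys[j]) + go(i + 1, j + 1, "M"))
            if i < len(xs):
                cost = gap_extend if last == "X" else gap_open
                best = max(best, cost + go(i + 1, j, "X"))
            if j < len(ys):
                cost = gap_extend if last == "Y" else gap_open
                best = max(best, cost + go(i, j + 1, "Y"))
            return best

        return go(0, 0, "M")

    best = 0.0
    for i0 in range(len(x)):
        for i1 in range(i0 + 1, len(x) + 1):
            for j0 in range(len(y)):
                for j1 in range(j0 + 1, len(y) + 1):
                    best = max(best, global_best(x[i0:i1], y[j0:j1]))
    return best


def identity_pair_score(match: float, mismatch: float):
    return lambda a, b: match if a == b else mismatch


def complementarity_pair_score(wc: float = 5.0, wobble: float = 1.0, mismatch: float = -3.0):
    wc_pairs = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    gu = {("G", "U"), ("U", "G")}

    def s(a: str, b: str) -> float:
        if (a, b) in wc_pairs:
            return wc
        if (a, b) in gu:
            return wobble
        return mismatch

    return s


def best_duplex_score(query: str, target: str, **scheme) -> float:
    """Antiparallel convention: the query is reversed before scoring."""
    return best_local_alignment_score(
        query[::-1], target, complementarity_pair_score(), scheme.get("gap_open", -9.0),
        scheme.get("gap_extend", -4.0),
    )


def bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up by the literal definition."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adjusted = [0.0] * n
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, n * pvals[i] / rank_from_top)
        adjusted[i] = min(1.0, running_min)
    return adjusted


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by direct combinatorial summation."""
    denom = math.comb(N, n)
    total = 0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom


def welch_t(x1: list[float], x2: list[float]) -> tuple[float, float]:
    """Welch t statistic and degrees of freedom from the closed form."""
    n1, n2 = len(x1), len(x2)
    m1, m2 = sum(x1) / n1, sum(x2) / n2
    v1 = sum((v - m1) ** 2 for v in x1) / (n1 - 1)
    v2 = sum((v - m2) ** 2 for v in x2) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    t = (m2 - m1) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, df
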