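"""Independent brute-force oracles for the exact tests and clustering.

These deliberately re-derive every quantity from first principles
(enumeration over the sample space) and never call the implementation or
scipy, so the test suite can compare two independent routes.
"""

from itertools import combinations
from math import comb

_EPS = 1e-12


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by hypergeometric enumeration of the 2x2 table.

    Margins fixed at (a+b, c+d, a+c, b+d); sums the probabilities of all
    tables no more likely than the observed one.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = pmf(a)
    return min(
        1.0,
        sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + _EPS)),
    )


def binomial_two_sided(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p: sum over outcomes no more likely than k."""
    def pmf(x: int) -> float:
        return comb(n, x) * p0 ** x * (1 - p0) ** (n - x)

    p_obs = pmf(k)
    return min(1.0, sum(pmf(x) for x in range(n + 1) if pmf(x) <= p_obs * (1 + _EPS)))


def wilcoxon_two_sided(x, y) -> float:
    """Exact two-sided rank-sum p by full enumeration of group assignments.

    Counts arrangements whose U statistic deviates from its mean at least as
    much as observed.  Assumes tie-free data.
    """
    pooled = sorted(list(x) + list(y))
    n1, n2 = len(x), len(y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}

    def u_of(group):
        r = sum(ranks[v] for v in group)
        return r - n1 * (n1 + 1) / 2

    mu = n1 * n2 / 2
    u_obs = abs(u_of(x) - mu)
    total = 0
    extreme = 0
    for idx in combinations(range(n1 + n2), n1):
        group = [pooled[i] for i in idx]
        total += 1
        if abs(u_of(group) - mu) >= u_obs - _EPS:
            extreme += 1
    return extreme / total


def bh_step_up(pvalues) -> list:
    """Benjamini-Hochberg adjusted p-values by the step-up definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(pvalues[i] * m / rank_from_top, prev)
        adj[i] = val
        prev = val
    return adj


def single_linkage_brute(positions, max_gap: int):
    """O(n^2) single-linkage clustering of 1-D positions by repeated merging."""
    clusters = [{p} for p in set(positions)]
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if any(
                    abs(p - q) <= max_gap for p in clusters[i] for q in clusters[j]
                ):
                    clusters[i] |= clusters[j]
                    del clusters[j]
                    merged = True
                    break
            if merged:
                break
    return sorted(sorted(c) for c in clusters)
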