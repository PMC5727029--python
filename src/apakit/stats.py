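"""Shared statistical primitives.

Thin, convention-normalising wrappers around scipy and statsmodels: every
test here is two-sided, exact where the backend is exact, and returns a
:class:`StatResult` so downstream tables carry a uniform (statistic, p,
method) triple.  Also houses the library-size helpers (median-of-ratios
size factors, pseudocounted log2 ratios) used by several analysis stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "fisher_exact",
    "binomial_test",
    "wilcoxon_rank_sum",
    "bh_fdr",
    "size_factors",
    "log2_ratio",
]


@dataclass(frozen=True)
class StatResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        p = self.p_value
        if np.isfinite(p) and not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {p}")


def fisher_exact(table) -> StatResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    A table with any zero margin carries no information about association;
    by convention we return p = 1 rather than raise.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("fisher_exact expects a non-negative 2x2 table")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        return StatResult(np.nan, 1.0, "fisher-exact")
    odds, p = _sps.fisher_exact(t, alternative="two-sided")
    return StatResult(float(odds), float(min(p, 1.0)), "fisher-exact")


def binomial_test(k: int, n: int, p0: float) -> StatResult:
    """Exact two-sided binomial test of k successes in n trials vs p0.

    Two-sided p sums the probabilities of all outcomes no more likely than
    the observed one.  n = 0 is undefined and returns NaN.
    """
    if n == 0:
        return StatResult(np.nan, np.nan, "binomial-exact")
    res = _sps.binomtest(int(k), int(n), float(p0), alternative="two-sided")
    return StatResult(float(k), float(res.pvalue), "binomial-exact")


def wilcoxon_rank_sum(x, y, exact_max: int = 12) -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration when the pooled sample is small (n1 + n2 <= exact_max)
    and tie-free; otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_rank_sum requires non-empty samples")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= exact_max and tie_free) else "asymptotic"
    res = _sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return StatResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      f"wilcoxon-{method}")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1.

    NaN entries are passed through as NaN and do not count toward the number
    of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("bh_fdr requires a non-empty p-value vector")
    q = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors (rows = features, cols = samples).

    The reference is the per-feature geometric mean across samples, computed
    over features with all-positive counts; each sample's factor is the
    median of its ratios to that reference.  Falls back to column-sum scaling
    when no feature is everywhere positive.
    """
    m = counts.to_numpy(dtype=float)
    positive = (m > 0).all(axis=1)
    if positive.sum() >= 1:
        logref = np.log(m[positive]).mean(axis=1)
        sf = np.exp(np.median(np.log(m[positive]) - logref[:, None], axis=0))
    else:
        total = m.sum(axis=0)
        sf = total / np.exp(np.mean(np.log(np.where(total > 0, total, 1.0))))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def log2_ratio(numerator: float, denominator: float, pseudocount: float = 0.5) -> float:
    """log2((numerator + pc) / (denominator + pc)); pc avoids infinities."""
    return float(np.log2((numerator + pseudocount) / (denominator + pseudocount)))
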