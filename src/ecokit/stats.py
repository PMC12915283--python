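"""Exact small-sample nonparametric tests and multiple-comparison helpers.

The experiments this pipeline serves have 6-7 animals per group, where
normal approximations to rank-test null distributions are poor.  The tests
here compute exact, tie-aware p-values by enumeration below a documented
sample-size cutoff and fall back to scipy's asymptotic machinery above it.

Two-sided exact p-values use the convention ``p = min(1, 2*min(P(T <= t),
P(T >= t)))`` on the enumerated null distribution; for Spearman the exact
p enumerates permutations of one margin and counts ``|rho| >= |rho_obs|``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from math import comb, factorial

import numpy as np
from scipy import stats as sps

from .exceptions import InputError

#: largest pooled sample size for which rank-test nulls are enumerated exactly
EXACT_ENUMERATION_LIMIT = 12

#: largest n for which the Spearman permutation null is enumerated exactly
SPEARMAN_EXACT_LIMIT = 8


@dataclass(frozen=True)
class TestResult:
    """Statistic and p-value of a single hypothesis test."""

    statistic: float
    p: float
    exact: bool


def _tail_p_two_sided(null: np.ndarray, observed: float) -> float:
    lo = np.mean(null <= observed + 1e-12)
    hi = np.mean(null >= observed - 1e-12)
    return float(min(1.0, 2.0 * min(lo, hi)))


def _rankdata(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled)


def mann_whitney_exact(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test, exact by enumeration for small samples.

    ``statistic`` is U for the first sample.  Exact p-values enumerate all
    C(n+m, n) assignments of the pooled (tie-aware) ranks when
    ``n + m <= EXACT_ENUMERATION_LIMIT``; otherwise scipy's tie-corrected
    normal approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be nonempty")
    n, m = x.size, y.size
    ranks = _rankdata(np.concatenate([x, y]))
    u_obs = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    if n + m <= EXACT_ENUMERATION_LIMIT:
        idx = range(n + m)
        null = np.fromiter(
            (ranks[list(c)].sum() for c in combinations(idx, n)),
            dtype=float,
            count=comb(n + m, n),
        ) - n * (n + 1) / 2.0
        p = _tail_p_two_sided(null, u_obs)
        return TestResult(u_obs, p, exact=True)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(float(res.statistic), float(res.pvalue), exact=False)


def wilcoxon_exact(x, y=None) -> TestResult:
    """Two-sided Wilcoxon signed-rank test, exact for small samples.

    Accepts paired samples (or a single array of differences).  Zero
    differences are dropped (Wilcoxon's original policy).  Exact p-values
    enumerate all 2**n sign assignments of the tie-aware absolute-difference
    ranks when the number of nonzero differences is at most
    ``EXACT_ENUMERATION_LIMIT``.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise InputError("all differences are zero; test undefined")
    n = d.size
    ranks = _rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    if n <= EXACT_ENUMERATION_LIMIT:
        signs = np.array(list(np.ndindex(*(2,) * n)), dtype=float)  # (2**n, n)
        null = signs @ ranks
        p = _tail_p_two_sided(null, w_obs)
        return TestResult(w_obs, p, exact=True)
    res = sps.wilcoxon(d, alternative="two-sided", method="approx")
    return TestResult(float(res.statistic), float(res.pvalue), exact=False)


def spearman_exact(x, y) -> TestResult:
    """Spearman rank correlation with a two-sided p-value.

    For ``n <= SPEARMAN_EXACT_LIMIT`` the p-value is exact, enumerating all
    n! permutations of one margin and counting ``|rho| >= |rho_obs|``;
    above that scipy's t-approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputError("paired samples must have equal length")
    n = x.size
    if n < 4:
        raise InputError("Spearman correlation requires n >= 4")
    rx = _rankdata(x)
    ry = _rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise InputError("degenerate (constant-rank) input")
    rho_obs = float(np.corrcoef(rx, ry)[0, 1])
    if n <= SPEARMAN_EXACT_LIMIT:
        rx_c = rx - rx.mean()
        denom = np.sqrt((rx_c**2).sum())
        count = 0
        total = factorial(n)
        for perm in permutations(range(n)):
            ry_p = ry[list(perm)]
            ry_c = ry_p - ry_p.mean()
            rho = float(rx_c @ ry_c) / (denom * np.sqrt((ry_c**2).sum()))
            if abs(rho) >= abs(rho_obs) - 1e-12:
                count += 1
        return TestResult(rho_obs, count / total, exact=True)
    res = sps.spearmanr(x, y)
    return TestResult(float(res.statistic), float(res.pvalue), exact=False)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0, 1]")
    return sps.false_discovery_control(p, method="bh")


def count_derangements(n: int) -> int:
    """Number of permutations of n items with no fixed point (inclusion-exclusion)."""
    if n < 0:
        raise InputError("n must be nonnegative")
    return sum((-1) ** k * factorial(n) // factorial(k) for k in range(n + 1))
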