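"""Nonparametric statistics used throughout the pipeline.

The workhorse here is an exact small-sample Wilcoxon signed-rank test: with
cohorts of n = 8 subjects the normal approximation is badly calibrated and
the attainable two-sided p-value floor is 2/2**8 = 0.0078125, which is why
group contrasts in which every subject moves the same way bottom out at
q = 0.0078 after FDR adjustment.  The exact null distribution is computed by
dynamic programming over signed-rank sums (equivalent to enumerating all 2**n
sign assignments), with average ranks for tied magnitudes.

Benjamini-Hochberg and Friedman are implemented directly (Friedman with the
tie-safe average-rank formula); Kolmogorov-Smirnov, paired t and
Kruskal-Wallis delegate to scipy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "wilcoxon_signed_rank",
    "benjamini_hochberg",
    "ks_normality",
    "paired_t_test",
    "friedman",
    "kruskal_wallis",
]

#: switch-over point between exact enumeration and the tie-corrected
#: normal approximation for the Wilcoxon signed-rank test
WILCOXON_EXACT_MAX_N = 25


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test."""

    statistic: float
    p: float
    n: int
    method: str
    two_sided: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p-value out of range: {self.p}")


def _signed_rank_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """Exact null distribution of the positive-rank sum.

    ``doubled_ranks`` are 2x the (possibly tied, average) ranks so they are
    integers.  Returns counts over the doubled statistic 0..sum(doubled_ranks);
    counts[w] = number of the 2**n sign assignments with doubled W+ == w.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(diffs: np.ndarray) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (logged).  For n <= 25 the p-value is exact
    (full enumeration of sign assignments, average ranks for ties); above
    that a tie-corrected normal approximation with continuity correction is
    used.

    Raises
    ------
    ValueError
        If all differences are zero (the statistic is undefined).
    """
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 1:
        raise ValueError("diffs must be 1-D")
    nonzero = d[d != 0]
    n_dropped = d.size - nonzero.size
    if n_dropped:
        logger.info("wilcoxon_signed_rank: dropped %d zero difference(s)", n_dropped)
    if nonzero.size == 0:
        raise ValueError("all paired differences are zero; Wilcoxon statistic undefined")

    n = nonzero.size
    ranks = sps.rankdata(np.abs(nonzero))  # average ranks on ties
    w_plus = float(ranks[nonzero > 0].sum())

    if n <= WILCOXON_EXACT_MAX_N:
        doubled = np.rint(2 * ranks).astype(int)
        counts = _signed_rank_distribution(doubled)
        total = counts.sum()  # == 2**n
        w2 = int(round(2 * w_plus))
        cdf = counts[: w2 + 1].sum() / total
        sf = counts[w2:].sum() / total  # includes P(W == w)
        p = min(1.0, 2.0 * min(cdf, sf))
        method = "wilcoxon-exact"
    else:
        mean = n * (n + 1) / 4.0
        # tie correction on the variance
        _, tie_counts = np.unique(np.abs(nonzero), return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
        method = "wilcoxon-normal"

    return TestResult(statistic=w_plus, p=float(p), n=n, method=method)


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, mapped back
    to the input order and clipped to [0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def ks_normality(sample: np.ndarray, alpha: float = 0.05) -> TestResult:
    """Kolmogorov-Smirnov test against a normal with the sample's mean/sd.

    Used only as a gate for choosing Wilcoxon over the t-test.  Estimating
    the normal parameters from the same sample makes the test conservative
    (the Lilliefors caveat); the gate errs toward the nonparametric branch
    for n < 4 by returning p = 0.
    """
    x = np.asarray(sample, dtype=float)
    n = x.size
    if n < 4:
        return TestResult(statistic=np.nan, p=0.0, n=n, method="ks-normality-smalln")
    sd = x.std(ddof=1)
    if sd == 0:
        return TestResult(statistic=1.0, p=0.0, n=n, method="ks-normality")
    stat, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return TestResult(statistic=float(stat), p=float(p), n=n, method="ks-normality")


def paired_t_test(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sided paired t-test on matched samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-D and the same length")
    if x.size < 2:
        raise ValueError(f"paired t-test needs n >= 2, got n={x.size}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # x == y gives 0/0
        stat, p = sps.ttest_rel(x, y)
    if np.isnan(stat):  # identical samples: no evidence against the null
        stat, p = 0.0, 1.0
    return TestResult(statistic=float(stat), p=float(p), n=x.size, method="paired-t")


def friedman(blocks: np.ndarray) -> TestResult:
    """Friedman test on an (n_blocks, k_treatments) table.

    Ranks within blocks use average ranks; the statistic uses the tie-safe
    form  Q = (k-1) * sum_j (R_j - n(k+1)/2)^2 / (sum_ij r_ij^2 - nk(k+1)^2/4)
    referred to a chi-squared distribution with k-1 degrees of freedom.
    Identical blocks (zero rank variance) give Q = 0, p = 1.
    """
    b = np.asarray(blocks, dtype=float)
    if b.ndim != 2 or b.shape[0] < 2 or b.shape[1] < 2:
        raise ValueError(f"blocks must be (n>=2, k>=2), got shape {b.shape}")
    n, k = b.shape
    r = np.apply_along_axis(sps.rankdata, 1, b)
    col_sums = r.sum(axis=0)
    num = (k - 1) * ((col_sums - n * (k + 1) / 2.0) ** 2).sum()
    den = (r**2).sum() - n * k * (k + 1) ** 2 / 4.0
    if den == 0:  # all blocks fully tied
        return TestResult(statistic=0.0, p=1.0, n=n, method="friedman")
    q = num / den
    p = float(sps.chi2.sf(q, k - 1))
    return TestResult(statistic=float(q), p=p, n=n, method="friedman")


def kruskal_wallis(groups: list[np.ndarray]) -> TestResult:
    """Kruskal-Wallis H-test across independent groups (tie-corrected)."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrs):
        if g.size < 2:
            raise ValueError(f"group {i} has size {g.size}; need >= 2")
    if all(np.all(g == arrs[0][0]) for g in arrs):
        n = sum(g.size for g in arrs)
        return TestResult(statistic=0.0, p=1.0, n=n, method="kruskal-wallis")
    stat, p = sps.kruskal(*arrs)
    n = sum(g.size for g in arrs)
    return TestResult(statistic=float(stat), p=float(p), n=n, method="kruskal-wallis")
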