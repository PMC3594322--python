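"""Exact statistics for small imaging cohorts.

Three tests back the assay's comparisons:

* Fisher's exact test on a 2×2 contingency table (positive vs. the pooled
  absent + cannot-call counts of two constructs), two-sided by summing the
  hypergeometric probabilities of all tables, at fixed margins, that are no
  more probable than the observed one.
* The exact Wilcoxon rank-sum test on two CER samples.  The null
  distribution of the rank sum is computed exactly for any sample sizes by
  a generalized shift algorithm (dynamic program over doubled mid-ranks, so
  ties are handled exactly); the two-sided p doubles the smaller tail,
  capped at 1.
* An Anderson–Darling normality screen with mean and SD estimated from the
  sample, using the small-sample adjusted statistic
  A²* = A²·(1 + 0.75/n + 2.25/n²) against the α = 0.05 critical value
  0.752; an approximate p-value comes from the standard piecewise
  exponential formula for the adjusted statistic.

Group sizes in this assay are small (8–14 cells), which is exactly where
exact null distributions matter; the implementations here stay exact at
any size rather than switching to normal approximations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "anderson_darling_normal",
    "fisher_exact",
    "wilcoxon_exact",
]

#: α = 0.05 critical value for the adjusted Anderson–Darling statistic when
#: both mean and variance are estimated from the sample.
AD_CRITICAL_005 = 0.752


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2×2 table of counts; rows = constructs, cols = positive vs. rest."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("counts must be non-negative integers")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("table total must be >= 1")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    exact: bool
    details: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value must lie in [0, 1]")


def fisher_exact(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher's exact test by summed smaller probabilities.

    All tables with the observed margins whose hypergeometric probability
    is at most that of the observed table (within a 1e-12 relative
    tolerance, to absorb float rounding of exact ties) contribute to p.
    A table with an empty margin carries no information: p = 1 with a
    warning.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1 = a + b, c + d, a + c
    n = table.total
    if min(r1, r2, c1, n - c1) == 0:
        warnings.warn("degenerate 2x2 table (empty margin); p = 1", stacklevel=2)
        return TestResult(np.nan, 1.0, "fisher_exact", True)
    dist = sps.hypergeom(n, r1, c1)
    k = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = dist.pmf(k)
    p_obs = dist.pmf(a)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())
    p = min(1.0, p)
    odds = np.inf if b * c == 0 else (a * d) / (b * c)
    return TestResult(float(odds), p, "fisher_exact", True, {"p_observed_table": float(p_obs)})


def _rank_sum_distribution(doubled_ranks: np.ndarray, n: int) -> np.ndarray:
    """Exact null pmf of the doubled rank sum of a size-``n`` subset.

    Shift-algorithm dynamic program over the multiset of doubled mid-ranks
    (integers): ``dp[j, s]`` counts size-``j`` subsets with doubled rank
    sum ``s``.  Counts stay below 2^53 for any cohort this assay meets, so
    float64 accumulation is exact.
    """
    total = int(doubled_ranks.sum())
    dp = np.zeros((n + 1, total + 1))
    dp[0, 0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        # descending j so each value is used at most once
        for j in range(n, 0, -1):
            dp[j, r:] += dp[j - 1, : total + 1 - r]
    counts = dp[n]
    return counts / counts.sum()


def wilcoxon_exact(x, y) -> TestResult:
    """Exact two-sided Wilcoxon rank-sum test.

    The statistic is the sum of the (mid-)ranks of ``x`` in the pooled
    sample.  Under the null every assignment of ranks to the two groups is
    equally likely; the exact distribution is computed by the shift
    algorithm over doubled mid-ranks (integers even with ties).  Two-sided
    p doubles the smaller of P(W ≤ w) and P(W ≥ w), capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("all values tied across both samples; p = 1", stacklevel=2)
        return TestResult(x.size * (pooled.size + 1) / 2.0, 1.0, "wilcoxon_exact", True)
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    doubled = np.rint(2.0 * ranks).astype(np.int64)
    n = x.size
    w2 = int(doubled[:n].sum())  # doubled rank sum of x
    pmf = _rank_sum_distribution(doubled, n)
    lo = float(pmf[: w2 + 1].sum())
    hi = float(pmf[w2:].sum())
    p = min(1.0, 2.0 * min(lo, hi))
    return TestResult(w2 / 2.0, p, "wilcoxon_exact", True,
                      {"n_x": int(n), "n_y": int(y.size), "tail_low": lo, "tail_high": hi})


def anderson_darling_normal(x) -> TestResult:
    """Anderson–Darling normality screen (mean and SD estimated).

    Requires n ≥ 8 and a non-degenerate sample.  Reports the adjusted
    statistic A²* and an approximate p-value (piecewise exponential fit);
    ``details["reject_at_005"]`` compares A²* with the 0.752 critical
    value.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 8:
        raise ValueError(f"Anderson-Darling screen needs n >= 8, got {n}")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("zero variance: constant sample")
    z = (x - x.mean()) / s
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (sps.norm.logcdf(z) + sps.norm.logsf(z[::-1])))
    a2_star = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    p = _ad_p_value(a2_star)
    return TestResult(
        float(a2_star),
        float(p),
        "anderson_darling_normal",
        False,
        {"a2": float(a2), "reject_at_005": bool(a2_star > AD_CRITICAL_005),
         "critical_005": AD_CRITICAL_005},
    )


def _ad_p_value(a2_star: float) -> float:
    """Approximate p for the adjusted A² statistic (D'Agostino & Stephens)."""
    a = a2_star
    if a >= 0.6:
        p = np.exp(1.2937 - 5.709 * a + 0.0186 * a * a)
    elif a > 0.34:
        p = np.exp(0.9177 - 4.279 * a - 1.38 * a * a)
    elif a > 0.2:
        p = 1.0 - np.exp(-8.318 + 42.796 * a - 59.938 * a * a)
    else:
        p = 1.0 - np.exp(-13.436 + 101.14 * a - 223.73 * a * a)
    return float(min(1.0, max(0.0, p)))
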