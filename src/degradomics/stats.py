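"""Exact statistics used throughout the pipeline.

Everything here is computed from first principles: the hypergeometric mass in
log-space (log-gamma factorials, no factorial tables), Fisher's exact test by
tail summation over the conditional distribution, the Mann-Whitney-Wilcoxon
rank-sum test with an exact small-sample mode based on a rank-sum counting
recurrence, and a pooled one-sided two-proportion z test with its companion
one-sided Fisher p for the same table.

Conventions
-----------
* One-sided Fisher tests enrichment of cell ``a`` (upper tail).
* Two-sided Fisher sums all tables with the observed margins whose
  probability does not exceed the observed table's (with a small relative
  tolerance guarding float equality), matching mainstream implementations.
* p-values are clipped into (0, 1].
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm
from scipy.stats import wilcoxon as _scipy_wilcoxon

__all__ = [
    "Sidedness",
    "TestResult",
    "ContingencyTable2x2",
    "hypergeom_pmf",
    "fisher_exact",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "proportion_test_one_sided",
]

_TWO_SIDED_TOL = 1.0 + 1e-7


class Sidedness(str, enum.Enum):
    ONE_SIDED = "one_sided"
    TWO_SIDED = "two_sided"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    sidedness: Sidedness
    method: str
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must lie in (0, 1], got {self.p_value}")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 count table; rows = list membership, columns = category."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @classmethod
    def from_rows(cls, rows: Sequence[Sequence[int]]) -> "ContingencyTable2x2":
        (a, b), (c, d) = rows
        return cls(a, b, c, d)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)


def _log_comb(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -math.inf
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    """P(X = k) for X ~ Hypergeometric(N, K, n).

    N: population size, K: successes in the population, n: draws.  Returns 0
    for k outside the support.  Computed in log-space so large counts do not
    overflow.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K <= N and 0 <= n <= N, got N={N}, K={K}, n={n}")
    if k < max(0, n + K - N) or k > min(n, K):
        return 0.0
    return math.exp(_log_comb(K, k) + _log_comb(N - K, n - k) - _log_comb(N, n))


def _clip_p(p: float) -> float:
    return min(1.0, max(p, 5e-324))


def fisher_exact(
    table: ContingencyTable2x2 | Sequence[Sequence[int]],
    sidedness: Sidedness | str = Sidedness.TWO_SIDED,
) -> TestResult:
    """Fisher's exact test on a 2x2 table.

    The conditional distribution of cell ``a`` given the margins is
    hypergeometric; the one-sided p sums the upper tail (enrichment of
    ``a``), the two-sided p sums every table at least as improbable as the
    observed one.  A zero margin makes the table untestable: p = 1 with a
    warning.
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2.from_rows(table)
    sidedness = Sidedness(sidedness)
    a, b, c, d = table.a, table.b, table.c, table.d
    N = table.total
    r1, c1 = a + b, a + c
    stat = table.odds_ratio()
    if r1 == 0 or c1 == 0 or r1 == N or c1 == N:
        warnings.warn("degenerate 2x2 table (zero margin); p set to 1", stacklevel=2)
        return TestResult(stat, 1.0, sidedness, "fisher_exact")
    lo, hi = max(0, r1 + c1 - N), min(r1, c1)
    pmf = {k: hypergeom_pmf(k, N, c1, r1) for k in range(lo, hi + 1)}
    if sidedness is Sidedness.ONE_SIDED:
        p = sum(pmf[k] for k in range(a, hi + 1))
    else:
        cutoff = pmf[a] * _TWO_SIDED_TOL
        p = sum(v for v in pmf.values() if v <= cutoff)
    return TestResult(stat, _clip_p(p), sidedness, "fisher_exact")


# ---------------------------------------------------------------------------
# Mann-Whitney-Wilcoxon rank-sum test
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{(i,j): x_i > y_j} + 0.5 * #ties, via pairwise comparison."""
    diff = x[:, None] - y[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def _exact_u_counts(m: int, n: int) -> np.ndarray:
    """counts[u] = #labelings of ranks 1..m+n into x of size m with U = u.

    Classic rank-sum recurrence: choosing which of the N ranks belong to x,
    track the x rank-sum; U = ranksum - m(m+1)/2.  Total sums to C(m+n, m).
    """
    N = m + n
    max_sum = sum(range(N - m + 1, N + 1))
    # ways[j][s]: subsets of size j of {1..i} with sum s (i advances in loop)
    ways = np.zeros((m + 1, max_sum + 1), dtype=float)
    ways[0, 0] = 1.0
    for i in range(1, N + 1):
        for j in range(min(i, m), 0, -1):
            ways[j, i:] += ways[j - 1, : max_sum + 1 - i]
    min_sum = m * (m + 1) // 2
    return ways[m, min_sum : min_sum + m * n + 1]  # index = U value


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    sidedness: Sidedness | str = Sidedness.TWO_SIDED,
    exact_limit: int = 12,
) -> TestResult:
    """Mann-Whitney-Wilcoxon rank-sum test for two independent samples.

    Exact p by the rank-sum counting distribution when the combined size is
    at most ``exact_limit`` and there are no ties; otherwise the normal
    approximation with tie-corrected variance and continuity correction.
    The one-sided p is the tail in the observed direction.  If every value
    in both samples is identical the test is vacuous and p = 1.
    """
    sidedness = Sidedness(sidedness)
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    m, n = x.size, y.size
    u = _u_statistic(x, y)
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < combined.size

    if np.all(combined == combined[0]):
        return TestResult(u, 1.0, sidedness, "mann_whitney (degenerate)")

    if m + n <= exact_limit and not has_ties:
        counts = _exact_u_counts(m, n)
        total = counts.sum()
        ui = int(round(u))
        p_le = counts[: ui + 1].sum() / total
        p_ge = counts[ui:].sum() / total
        one = min(p_le, p_ge)
        p = one if sidedness is Sidedness.ONE_SIDED else min(1.0, 2.0 * one)
        return TestResult(u, _clip_p(p), sidedness, "mann_whitney (exact)")

    # normal approximation, tie-corrected variance, continuity correction
    N = m + n
    mu = m * n / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = m * n / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return TestResult(u, 1.0, sidedness, "mann_whitney (degenerate)")
    z = (abs(u - mu) - 0.5) / math.sqrt(var)
    one = float(norm.sf(max(z, 0.0)))
    p = one if sidedness is Sidedness.ONE_SIDED else min(1.0, 2.0 * one)
    return TestResult(u, _clip_p(p), sidedness, "mann_whitney (normal approx)")


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float],
    sidedness: Sidedness | str = Sidedness.TWO_SIDED,
) -> TestResult:
    """Paired signed-rank variant (not the default unpaired method)."""
    sidedness = Sidedness(sidedness)
    alternative = "two-sided" if sidedness is Sidedness.TWO_SIDED else "greater"
    res = _scipy_wilcoxon(list(x), list(y), alternative=alternative)
    return TestResult(
        float(res.statistic), _clip_p(float(res.pvalue)), sidedness,
        "wilcoxon_signed_rank (scipy)",
    )


def proportion_test_one_sided(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Pooled-variance z test of H1: p1 > p2, with the companion Fisher p.

    Degenerate pooled variance (all successes or all failures) yields z = 0,
    p = 0.5.  The one-sided Fisher p for the same 2x2 table is reported in
    ``extra["fisher_one_sided_p"]`` because the exact test is the natural
    companion at these sample sizes.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("success counts must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    z = 0.0 if var == 0 else (p1 - p2) / math.sqrt(var)
    p = float(norm.sf(z))
    fisher_p = fisher_exact(
        ContingencyTable2x2(k1, n1 - k1, k2, n2 - k2), Sidedness.ONE_SIDED
    ).p_value
    return TestResult(
        z,
        _clip_p(p),
        Sidedness.ONE_SIDED,
        "two_proportion_z (pooled)",
        extra={"fisher_one_sided_p": fisher_p, "p1": p1, "p2": p2},
    )
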