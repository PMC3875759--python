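"""Exact-statistics machinery against brute-force and scipy oracles."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats as ss
from hypothesis import given
from hypothesis import strategies as st

from degradomics import (
    ContingencyTable2x2,
    Sidedness,
    fisher_exact,
    hypergeom_pmf,
    mann_whitney,
    proportion_test_one_sided,
    wilcoxon_signed_rank,
)
from degradomics.stats import TestResult as StatTestResult

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def fisher_oracle(a, b, c, d, sided):
    """Enumerate all tables with the observed margins using exact fractions."""
    r1, c1, N = a + b, a + c, a + b + c + d

    def prob(k):  # P(cell a = k | margins), multivariate hypergeometric
        if k < 0 or k > r1 or c1 - k < 0 or c1 - k > N - r1:
            return Fraction(0)
        return Fraction(math.comb(r1, k) * math.comb(N - r1, c1 - k), math.comb(N, c1))

    support = [k for k in range(0, min(r1, c1) + 1) if prob(k) > 0]
    p_obs = prob(a)
    if sided == "one_sided":
        p = sum(prob(k) for k in support if k >= a)
    else:
        p = sum(prob(k) for k in support if prob(k) <= p_obs)
    return float(p)


def mw_oracle(x, y, sided):
    """Enumerate every assignment of the pooled values to the two groups."""
    pooled = list(x) + list(y)
    m = len(x)
    idx = range(len(pooled))

    def u_of(sel):
        xs = [pooled[i] for i in sel]
        ys = [pooled[i] for i in idx if i not in sel]
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = u_of(tuple(range(m)))
    us = [u_of(sel) for sel in itertools.combinations(idx, m)]
    n_tot = len(us)
    p_le = sum(u <= u_obs for u in us) / n_tot
    p_ge = sum(u >= u_obs for u in us) / n_tot
    one = min(p_le, p_ge)
    return one if sided == "one_sided" else min(1.0, 2 * one)


# ---------------------------------------------------------------------------
# hypergeometric pmf
# ---------------------------------------------------------------------------

class TestHypergeomPmf:
    def test_enumerated_small_case(self):
        # 2 of 4 marked, draw 2: P(exactly 1 marked) = 4/6
        assert hypergeom_pmf(1, 4, 2, 2) == pytest.approx(2 / 3, abs=1e-14)

    def test_degenerate_full_draw(self):
        assert hypergeom_pmf(5, 5, 5, 5) == pytest.approx(1.0)

    @pytest.mark.parametrize("N,K,n", [(10, 4, 3), (50, 20, 12), (530, 266, 21)])
    def test_normalization(self, N, K, n):
        total = sum(
            hypergeom_pmf(k, N, K, n)
            for k in range(max(0, n + K - N), min(n, K) + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_out_of_support_is_zero(self):
        assert hypergeom_pmf(5, 10, 4, 4) == 0.0

    def test_matches_scipy(self, rng):
        for _ in range(50):
            N = int(rng.integers(2, 200))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(max(0, n + K - N), min(n, K) + 1))
            assert hypergeom_pmf(k, N, K, n) == pytest.approx(
                ss.hypergeom.pmf(k, N, K, n), rel=1e-10, abs=1e-14
            )


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

class TestFisherExact:
    def test_symmetric_table(self):
        assert fisher_exact([[1, 1], [1, 1]]).p_value == pytest.approx(1.0)

    def test_diagonal_table(self):
        # margins (2,2)/(2,2): three tables with prob 1/6, 2/3, 1/6
        assert fisher_exact([[2, 0], [0, 2]]).p_value == pytest.approx(1 / 3, abs=1e-12)

    def test_published_up_list_table(self):
        res = fisher_exact([[19, 2], [247, 262]])
        assert res.p_value < 0.001

    @pytest.mark.parametrize("sided", ["one_sided", "two_sided"])
    def test_against_enumeration_oracle_sampled(self, rng, sided):
        for _ in range(60):
            a, b, c, d = (int(v) for v in rng.integers(0, 7, size=4))
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            mine = fisher_exact([[a, b], [c, d]], sided).p_value
            assert mine == pytest.approx(fisher_oracle(a, b, c, d, sided), abs=1e-10)

    def test_against_scipy_two_sided(self, rng):
        for _ in range(40):
            a, b, c, d = (int(v) for v in rng.integers(0, 15, size=4))
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            assert fisher_exact([[a, b], [c, d]]).p_value == pytest.approx(
                ss.fisher_exact([[a, b], [c, d]])[1], rel=1e-8, abs=1e-12
            )

    def test_against_scipy_one_sided(self, rng):
        for _ in range(40):
            a, b, c, d = (int(v) for v in rng.integers(0, 12, size=4))
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            assert fisher_exact([[a, b], [c, d]], "one_sided").p_value == pytest.approx(
                ss.fisher_exact([[a, b], [c, d]], alternative="greater")[1],
                rel=1e-8,
            )

    def test_zero_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="margin"):
            res = fisher_exact([[0, 0], [3, 4]])
        assert res.p_value == 1.0

    def test_conservative_type_i_error_under_null(self, rng):
        """Under hypergeometric sampling with fixed margins, P(p <= 0.05)
        stays at or below 0.05 (+2 MC standard errors)."""
        reps = 10_000
        N, K, n = 40, 20, 12
        ks = rng.hypergeometric(K, N - K, n, size=reps)
        rejections = 0
        pcache = {}
        for k in ks:
            k = int(k)
            if k not in pcache:
                pcache[k] = fisher_exact([[k, n - k], [K - k, N - K - n + k]]).p_value
            rejections += pcache[k] <= 0.05
        mc_err = math.sqrt(0.05 * 0.95 / reps)
        assert rejections / reps <= 0.05 + 2 * mc_err

    def test_invalid_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


# ---------------------------------------------------------------------------
# Mann-Whitney-Wilcoxon
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_two_vs_two_one_sided(self):
        res = mann_whitney([1, 2], [3, 4], "one_sided")
        assert res.p_value == pytest.approx(1 / 6, abs=1e-12)

    def test_three_vs_three_one_sided(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6], "one_sided")
        assert res.p_value == pytest.approx(1 / 20, abs=1e-12)

    def test_identical_samples(self):
        assert mann_whitney([1, 2, 3], [1, 2, 3]).p_value == 1.0

    def test_all_values_identical(self):
        assert mann_whitney([2, 2], [2, 2]).p_value == 1.0

    @pytest.mark.parametrize("sided", ["one_sided", "two_sided"])
    def test_exact_mode_against_enumeration(self, rng, sided):
        for m in range(1, 6):
            for n in range(1, 6):
                if m + n > 10:
                    continue
                pooled = rng.choice(1000, size=m + n, replace=False).astype(float)
                x, y = pooled[:m], pooled[m:]
                mine = mann_whitney(x, y, sided).p_value
                assert mine == pytest.approx(mw_oracle(x, y, sided), abs=1e-12)

    def test_exact_mode_against_scipy(self, rng):
        for _ in range(20):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            mine = mann_whitney(x, y, "two_sided")
            sp = ss.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert mine.p_value == pytest.approx(sp.pvalue, abs=1e-12)

    def test_normal_approx_against_scipy_with_ties(self, rng):
        x = rng.integers(0, 5, size=20).astype(float)
        y = rng.integers(1, 6, size=25).astype(float)
        mine = mann_whitney(x, y, "two_sided")
        sp = ss.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert mine.p_value == pytest.approx(sp.pvalue, rel=1e-6)
        assert "approx" in mine.method

    @given(
        st.lists(st.integers(0, 500), min_size=2, max_size=8, unique=True),
        st.integers(1, 6),
        st.sampled_from(["exp", "cube", "affine"]),
    )
    def test_invariant_under_monotone_transform(self, pooled, m, fname):
        if m >= len(pooled):
            m = len(pooled) - 1
        x = [float(v) for v in pooled[:m]]
        y = [float(v) for v in pooled[m:]]
        f = {
            "exp": lambda v: math.exp(v / 100),
            "cube": lambda v: v**3,
            "affine": lambda v: 2.5 * v + 7,
        }[fname]
        p0 = mann_whitney(x, y).p_value
        p1 = mann_whitney([f(v) for v in x], [f(v) for v in y]).p_value
        assert p0 == pytest.approx(p1, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestWilcoxonSignedRank:
    def test_runs_and_labels(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 6], [2, 3, 4, 5, 1])
        assert 0 < res.p_value <= 1
        assert "signed_rank" in res.method


# ---------------------------------------------------------------------------
# two-proportion z test
# ---------------------------------------------------------------------------

class TestProportionTest:
    def test_equal_proportions(self):
        res = proportion_test_one_sided(5, 50, 5, 50)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(0.5)

    def test_extreme_difference(self):
        assert proportion_test_one_sided(50, 50, 0, 50).p_value < 1e-10

    def test_degenerate_all_zero(self):
        res = proportion_test_one_sided(0, 50, 0, 50)
        assert res.p_value == pytest.approx(0.5)
        assert res.extra["fisher_one_sided_p"] == pytest.approx(1.0)

    def test_against_closed_form_oracle(self):
        k1, n1, k2, n2 = 7, 50, 2, 50
        pooled = (k1 + k2) / (n1 + n2)
        z = (k1 / n1 - k2 / n2) / math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        res = proportion_test_one_sided(k1, n1, k2, n2)
        assert res.statistic == pytest.approx(z, abs=1e-12)
        assert res.p_value == pytest.approx(ss.norm.sf(z), abs=1e-9)
        assert res.extra["fisher_one_sided_p"] == pytest.approx(
            fisher_oracle(7, 43, 2, 48, "one_sided"), abs=1e-9
        )

    def test_input_validation(self):
        with pytest.raises(ValueError):
            proportion_test_one_sided(1, 0, 0, 5)
        with pytest.raises(ValueError):
            proportion_test_one_sided(6, 5, 0, 5)


class TestResultContract:
    def test_p_value_range_enforced(self):
        with pytest.raises(ValueError):
            StatTestResult(0.0, 0.0, Sidedness.ONE_SIDED, "x")
        with pytest.raises(ValueError):
            StatTestResult(0.0, 1.5, Sidedness.ONE_SIDED, "x")
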