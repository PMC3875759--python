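"""Tumor-volume arithmetic, baseline normalization, group summaries, and the
random-intercept growth model (validated against statsmodels MixedLM)."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

from degradomics import (
    GrowthMeasurement,
    GrowthSeries,
    Group,
    growth_curve_compare,
    normalize_to_baseline,
    summarize_groups,
    tumor_volume,
)
from degradomics.errors import ConfigurationError, ValidationError
from degradomics.simulate import simulate_xenograft
from degradomics.xenograft import _design, _ProfileLMM


class TestTumorVolume:
    @pytest.mark.parametrize("A,B,expected", [(10, 5, 100.0), (1, 1, 0.4)])
    def test_formula(self, A, B, expected):
        assert tumor_volume(A, B) == pytest.approx(expected)

    def test_dimension_order_enforced(self):
        with pytest.raises(ValidationError):
            tumor_volume(5, 10)

    @pytest.mark.parametrize("A,B", [(0, 0), (-1, -2), (3, 0)])
    def test_positivity(self, A, B):
        with pytest.raises(ValidationError):
            tumor_volume(A, B)

    def test_strictly_increasing_in_each_argument(self, rng):
        for _ in range(50):
            B = rng.uniform(1, 10)
            A = B + rng.uniform(0.1, 10)
            assert tumor_volume(A + 0.5, B) > tumor_volume(A, B)
            assert tumor_volume(A + 1, B + 0.5) > tumor_volume(A, B)


class TestNormalizeToBaseline:
    def test_doubling(self):
        assert normalize_to_baseline([(0, 2.0), (24, 4.0)]) == [(0, 1.0), (24, 2.0)]

    def test_constant_series(self):
        out = normalize_to_baseline([(0, 3.0), (24, 3.0), (48, 3.0)])
        assert all(r == 1.0 for _, r in out)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValidationError):
            normalize_to_baseline([(0, 0.0), (24, 4.0)])

    def test_unsorted_input_uses_earliest_time(self):
        out = normalize_to_baseline([(24, 4.0), (0, 2.0)])
        assert out[0] == (0, 1.0) and out[1] == (24, 2.0)


class TestSummarizeGroups:
    def _series(self, values_by_flank, group=Group.CONTROL, day=0.0):
        ms = [
            GrowthMeasurement(fid, group, day, signal=v)
            for fid, v in values_by_flank.items()
        ]
        return GrowthSeries(ms)

    def test_mean_and_sem(self):
        out = summarize_groups(self._series({"f1": 1.0, "f2": 3.0}))
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sem"] == pytest.approx(1.0)

    def test_identical_values_sem_zero(self):
        out = summarize_groups(self._series({"f1": 2.0, "f2": 2.0, "f3": 2.0}))
        assert out.iloc[0]["sem"] == pytest.approx(0.0)

    def test_single_observation_sem_missing(self):
        out = summarize_groups(self._series({"f1": 2.0}))
        assert math.isnan(out.iloc[0]["sem"])

    def test_simulation_coverage(self):
        """Group mean lies within 2 SEM of the truth in >= 95% of replicates
        (8 flanks per group, lognormal noise around a known trajectory)."""
        rng = np.random.default_rng(11)
        hits = total = 0
        for rep in range(200):
            s = simulate_xenograft(
                n_flanks=8, days=(0.0,), slope_control=0.0, slope_treated=0.0,
                intercept=2.0, flank_sd=0.0, noise_sd=0.1,
                rng=rng, output="signal",
            )
            out = summarize_groups(s)
            # noise is lognormal; truth of the mean is exp(mu + sd^2/2)
            truth = math.exp(2.0 + 0.1**2 / 2)
            for _, row in out.iterrows():
                total += 1
                hits += abs(row["mean"] - truth) <= 2 * row["sem"]
        assert hits / total >= 0.90


class TestGrowthSeriesValidation:
    def test_flank_in_two_groups_rejected(self):
        with pytest.raises(ValidationError):
            GrowthSeries(
                [
                    GrowthMeasurement("f", Group.CONTROL, 0, signal=1.0),
                    GrowthMeasurement("f", Group.TREATED, 1, signal=1.0),
                ]
            )

    def test_days_strictly_increasing(self):
        with pytest.raises(ValidationError):
            GrowthSeries(
                [
                    GrowthMeasurement("f", Group.CONTROL, 1, signal=1.0),
                    GrowthMeasurement("f", Group.CONTROL, 1, signal=2.0),
                ]
            )

    def test_measurement_kind_exclusive(self):
        with pytest.raises(ValidationError):
            GrowthMeasurement("f", Group.CONTROL, 0, A=5, B=3, signal=1.0)
        with pytest.raises(ValidationError):
            GrowthMeasurement("f", Group.CONTROL, 0)


class TestGrowthCurveCompare:
    def test_noiseless_slope_difference_recovery(self):
        s = simulate_xenograft(
            n_flanks=4, slope_control=0.2, slope_treated=0.05,
            flank_sd=0.0, noise_sd=0.0, seed=1,
        )
        fit = growth_curve_compare(s, transform="log", method="lmm")
        assert fit.fixed_effects["group_x_day"] == pytest.approx(-0.15, abs=1e-6)

    def test_identical_copy_groups_give_null_fit(self):
        rng = np.random.default_rng(3)
        days = (0.0, 7.0, 14.0, 21.0)
        ms = []
        for f in range(4):
            vals = np.exp(rng.normal(2.0, 0.5, size=len(days)))
            for grp, prefix in ((Group.CONTROL, "c"), (Group.TREATED, "t")):
                for d, v in zip(days, vals):
                    ms.append(GrowthMeasurement(f"{prefix}{f}", grp, d, signal=float(v)))
        fit = growth_curve_compare(GrowthSeries(ms), transform="log", method="lmm")
        assert fit.statistic == pytest.approx(0.0, abs=1e-7)
        assert fit.p_value == pytest.approx(1.0, abs=1e-6)

    def test_against_statsmodels_mixedlm(self):
        s = simulate_xenograft(
            n_flanks=6, slope_control=0.15, slope_treated=0.10,
            flank_sd=0.3, noise_sd=0.2, seed=7,
        )
        fit = growth_curve_compare(s, transform="log", method="lmm")
        df = s.to_frame()
        y = np.log(df["value"].to_numpy())
        X_alt, X_null, _, _ = _design(df)
        alt = MixedLM(y, X_alt, groups=df["flank_id"]).fit(reml=False)
        null = MixedLM(y, X_null, groups=df["flank_id"]).fit(reml=False)
        assert fit.statistic == pytest.approx(2 * (alt.llf - null.llf), abs=1e-5)
        for i, name in enumerate(("intercept", "day", "group", "group_x_day")):
            assert fit.fixed_effects[name] == pytest.approx(alt.fe_params[i], abs=1e-6)
        assert fit.sigma2_resid == pytest.approx(alt.scale, rel=1e-3)
        assert fit.sigma2_flank == pytest.approx(float(np.asarray(alt.cov_re)[0, 0]), rel=1e-2, abs=1e-6)

    def test_flank_relabeling_invariance(self):
        s = simulate_xenograft(n_flanks=4, seed=5)
        fit0 = growth_curve_compare(s, method="lmm")
        relabeled = GrowthSeries(
            [
                GrowthMeasurement(f"flank-{m.flank_id}-x", m.group, m.day, A=m.A, B=m.B)
                for m in s.measurements
            ]
        )
        fit1 = growth_curve_compare(relabeled, method="lmm")
        assert fit0.p_value == pytest.approx(fit1.p_value, rel=1e-9)

    def test_rescaling_invariance_after_log(self):
        s = simulate_xenograft(n_flanks=4, seed=9, output="signal")
        fit0 = growth_curve_compare(s, transform="log", method="lmm")
        scaled = GrowthSeries(
            [
                GrowthMeasurement(m.flank_id, m.group, m.day, signal=m.signal * 137.0)
                for m in s.measurements
            ]
        )
        fit1 = growth_curve_compare(scaled, transform="log", method="lmm")
        assert fit0.statistic == pytest.approx(fit1.statistic, abs=1e-6)
        assert fit1.fixed_effects["day"] == pytest.approx(fit0.fixed_effects["day"], abs=1e-8)

    def test_mixed_model_nests_ols(self):
        s = simulate_xenograft(n_flanks=5, flank_sd=0.4, noise_sd=0.2, seed=13)
        df = s.to_frame()
        y = np.log1p(df["value"].to_numpy())
        X_alt, _, _, _ = _design(df)
        model = _ProfileLMM(y, X_alt, df["flank_id"].to_numpy())
        assert model.fit()["loglik"] >= model.loglik(0.0) - 1e-9

    def test_interaction_recovery_within_3se(self):
        """Estimated slope difference within 3 SE of the truth in >= 95%
        of 200 replicates."""
        rng = np.random.default_rng(17)
        delta = -0.06
        hits = 0
        reps = 200
        for _ in range(reps):
            s = simulate_xenograft(
                n_flanks=8, slope_control=0.15, slope_treated=0.15 + delta,
                flank_sd=0.3, noise_sd=0.2, rng=rng, output="signal",
            )
            fit = growth_curve_compare(s, transform="log", method="lmm")
            est = fit.fixed_effects["group_x_day"]
            se = fit.fixed_effects_se["group_x_day"]
            hits += abs(est - delta) <= 3 * se
        assert hits / reps >= 0.95

    def test_power_with_large_slope_difference(self):
        """Slope difference of 3x residual sd per week: detected (p < 0.05)
        in >= 80% of simulations at 8 flanks per group."""
        rng = np.random.default_rng(23)
        reps, detected = 60, 0
        for _ in range(reps):
            s = simulate_xenograft(
                n_flanks=8, slope_control=0.15, slope_treated=0.15 - 3 * 0.2 / 7,
                flank_sd=0.3, noise_sd=0.2, rng=rng, output="signal",
            )
            fit = growth_curve_compare(s, transform="log", method="lmm")
            detected += fit.p_value < 0.05
        assert detected / reps >= 0.80

    def test_permutation_p_bounds_and_determinism(self):
        s = simulate_xenograft(n_flanks=4, seed=31)
        f1 = growth_curve_compare(s, method="permutation", n_perm=99, seed=5)
        f2 = growth_curve_compare(s, method="permutation", n_perm=99, seed=5)
        assert f1.p_value == f2.p_value
        assert 1 / 100 <= f1.p_value <= 1.0

    def test_design_validation(self):
        only_control = GrowthSeries(
            [
                GrowthMeasurement("a", Group.CONTROL, d, signal=1.0 + d)
                for d in (0.0, 1.0, 2.0)
            ]
        )
        with pytest.raises(ValidationError):
            growth_curve_compare(only_control)
        with pytest.raises(ConfigurationError):
            growth_curve_compare(only_control, transform="sqrt")
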