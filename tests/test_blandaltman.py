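"""Bland–Altman battery: plain, repeated-measures, modeled, and the gates."""

import numpy as np
import pytest

from sleepvalid.blandaltman import (
    BAResult,
    InsufficientDataError,
    ModeledBA,
    analyze_agreement,
    bias_from_loa,
    bootstrap_ci,
    normality_test,
    pearson_ci,
    rm_ba,
    simple_ba,
    heteroscedasticity_test,
    proportional_bias_test,
)


class TestSimpleBA:
    def test_unit_sd_construction(self):
        # diffs {1, 0, -1}: bias 0, SD 1, LOA (-1.96, +1.96)
        res = simple_ba(np.array([1.0, 0.0, -1.0]), np.zeros(3))
        assert res.bias == pytest.approx(0.0)
        assert res.sd_total == pytest.approx(1.0)
        assert res.loa_lower == pytest.approx(-1.96)
        assert res.loa_upper == pytest.approx(1.96)

    def test_constant_differences(self):
        res = simple_ba(np.full(5, 7.0), np.full(5, 4.0))
        assert res.bias == 3.0
        assert res.loa_lower == res.loa_upper == 3.0
        assert res.ci_bias == (3.0, 3.0)

    def test_loa_symmetry_invariant(self, rng):
        ref, dev = rng.normal(60, 5, 30), rng.normal(60, 5, 30)
        res = simple_ba(ref, dev)
        assert res.loa_lower + res.loa_upper == pytest.approx(2 * res.bias)

    def test_positive_bias_means_device_underestimates(self):
        res = simple_ba(np.array([10.0, 11.0, 12.0]), np.array([9.0, 10.0, 11.0]))
        assert res.bias == pytest.approx(1.0)

    def test_ci_formulas_against_direct_arithmetic(self, rng):
        ref = rng.normal(60, 5, 20)
        dev = ref - rng.normal(1, 2, 20)
        d = ref - dev
        res = simple_ba(ref, dev)
        from scipy import stats
        t = stats.t.ppf(0.975, 19)
        s = d.std(ddof=1)
        assert res.ci_bias[1] - res.ci_bias[0] == pytest.approx(2 * t * s / np.sqrt(20))
        assert res.ci_loa_upper[1] - res.ci_loa_upper[0] == pytest.approx(
            2 * t * s * np.sqrt(3 / 20)
        )

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            simple_ba(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestRepeatedMeasuresBA:
    def test_constant_differences_per_subject(self):
        groups = [np.full(4, 2.5), np.full(6, 2.5), np.full(3, 2.5)]
        res = rm_ba(groups)
        assert res.bias == 2.5
        assert res.var_between == res.var_within == 0.0
        assert res.loa_lower == res.loa_upper == 2.5

    def test_single_difference_falls_back_with_warning(self, rng):
        groups = [np.array([1.0]), np.array([2.0]), np.array([3.0])]
        with pytest.warns(UserWarning, match="falling back"):
            res = rm_ba(groups)
        direct = simple_ba(np.array([1.0, 2.0, 3.0]), np.zeros(3))
        assert res.bias == pytest.approx(direct.bias, abs=1e-10)
        assert res.sd_total == pytest.approx(direct.sd_total, abs=1e-10)

    def test_variance_components_recover_generating_sds(self):
        """m=30, n_i=200, sigma_b=1, sigma_w=2 -> sd_total near sqrt(5)."""
        rng = np.random.default_rng(2024)
        hits = 0
        reps = 200
        for _ in range(reps):
            groups = [
                0.5 + rng.normal(0, 1) + rng.normal(0, 2, size=200)
                for _ in range(30)
            ]
            res = rm_ba(groups)
            hits += abs(res.sd_total - np.sqrt(5.0)) <= 0.15
        assert hits / reps >= 0.95

    def test_components_match_reml_oracle(self):
        """One-way ANOVA components vs statsmodels MixedLM (REML) on
        small balanced instances (the two estimators coincide away from
        the variance boundary)."""
        import statsmodels.formula.api as smf
        import pandas as pd

        rng = np.random.default_rng(5)
        checked = 0
        for _ in range(20):
            m = int(rng.integers(8, 15))
            ni = int(rng.integers(10, 40))
            groups = [
                rng.normal(0, 1.0) + rng.normal(0, 1.5, size=ni)
                for _ in range(m)
            ]
            res = rm_ba(groups)
            df = pd.DataFrame({
                "d": np.concatenate(groups),
                "subj": np.repeat(np.arange(m), [len(g) for g in groups]),
            })
            fit = smf.mixedlm("d ~ 1", df, groups=df["subj"]).fit(reml=True)
            var_b = float(fit.cov_re.iloc[0, 0])
            var_w = float(fit.scale)
            sd_reml = np.sqrt(var_b + var_w)
            if var_b < 0.05:  # boundary fits are not comparable
                continue
            assert res.sd_total == pytest.approx(sd_reml, rel=0.02)
            checked += 1
        assert checked >= 10

class TestGates:
    def test_orthogonal_construction_gives_zero_slope(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        diff = np.array([1.0, -1.0, 0.0, -1.0, 1.0])  # orthogonal to centered ref
        fit = proportional_bias_test(ref, ref - diff)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_proportional_slope_recovery(self):
        rng = np.random.default_rng(3)
        ref = rng.uniform(40, 100, 500)
        diff = 5.0 - 0.1 * ref + rng.normal(0, 0.5, 500)
        fit = proportional_bias_test(ref, ref - diff)
        assert fit.intercept == pytest.approx(5.0, abs=0.5)
        assert fit.slope == pytest.approx(-0.1, abs=0.02)
        assert fit.p_slope < 0.05

    def test_homoscedastic_residuals_calibrate_the_246_multiplier(self):
        """2.46 x mean |e| recovers 1.96 sigma for normal errors."""
        rng = np.random.default_rng(4)
        sigma = 2.0
        ref = rng.uniform(40, 100, 2000)
        resid = rng.normal(0, sigma, 2000)
        fit = heteroscedasticity_test(ref, resid)
        assert fit.p_slope > 0.01  # no spurious heteroscedasticity signal
        assert 2.46 * fit.intercept == pytest.approx(1.96 * sigma, rel=0.05)

    def test_heteroscedastic_slope_recovery(self):
        """residual SD = 0.1 ref -> c1 within 15% of 0.1*sqrt(2/pi)."""
        rng = np.random.default_rng(6)
        ref = rng.uniform(40, 100, 2000)
        resid = rng.normal(0, 0.1 * ref)
        fit = heteroscedasticity_test(ref, resid)
        expected = 0.1 * np.sqrt(2 / np.pi)
        assert fit.slope == pytest.approx(expected, rel=0.15)
        assert fit.p_slope < 0.05

    def test_normality_gate_size_and_power(self):
        rng = np.random.default_rng(8)
        false_alarms = sum(
            normality_test(rng.normal(size=100))[1] < 0.05 for _ in range(200)
        )
        detections = sum(
            normality_test(rng.lognormal(size=100))[1] < 0.05 for _ in range(200)
        )
        assert false_alarms / 200 <= 0.10
        assert detections / 200 >= 0.95

    def test_normality_range_guard(self):
        with pytest.raises(ValueError, match="subsample"):
            normality_test(np.zeros(6000))


class TestBootstrapAndPearson:
    def test_constant_statistic_degenerate_interval(self):
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = bootstrap_ci(lambda d: 4.0, list(range(10)), B=200, seed=0)
        assert (lo, hi) == (4.0, 4.0)

    def test_bootstrap_coverage_for_the_mean(self):
        rng = np.random.default_rng(10)
        hits = 0
        reps = 300
        for i in range(reps):
            data = list(rng.normal(size=100))
            lo, hi = bootstrap_ci(np.mean, data, B=400, seed=i)
            hits += lo <= 0.0 <= hi
        assert abs(hits / reps - 0.95) <= 0.03

    def test_pearson_perfect_correlation(self):
        x = np.arange(10.0)
        res = pearson_ci(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.ci == (1.0, 1.0)
        res_neg = pearson_ci(x, -x)
        assert res_neg.r == pytest.approx(-1.0)

    def test_fisher_ci_coverage(self):
        rng = np.random.default_rng(11)
        hits = 0
        reps = 500
        rho = 0.8
        for _ in range(reps):
            x = rng.normal(size=50)
            y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=50)
            lo, hi = pearson_ci(x, y).ci
            hits += lo <= rho <= hi
        assert abs(hits / reps - 0.95) <= 0.03

    def test_ci_contains_r(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = pearson_ci(x, y)
        assert res.ci[0] <= res.r <= res.ci[1]
        assert -1 <= res.ci[0] and res.ci[1] <= 1


class TestAnalyzeAgreement:
    def test_error_free_channel_is_exactly_plain_zero(self):
        groups = [(np.full(20, 60.0 + i), np.full(20, 60.0 + i)) for i in range(4)]
        res = analyze_agreement(groups, mode="epoch")
        assert isinstance(res, BAResult)
        assert res.bias == 0.0
        assert res.loa_upper - res.loa_lower == 0.0

    def test_clean_gaussian_differences_take_the_plain_path(self):
        rng = np.random.default_rng(12)
        groups = []
        for _ in range(10):
            ref = rng.uniform(55, 75, 300)
            groups.append((ref, ref - rng.normal(0.5, 2.0, 300)))
        res = analyze_agreement(groups, mode="epoch", seed=1)
        assert isinstance(res, BAResult)
        assert res.bias == pytest.approx(0.5, abs=0.2)

    def test_multiplicative_error_triggers_log_modeled_path(self):
        """SOL-like positive data with multiplicative error: the log
        transform engages and proportional bias is flagged in >=90% of
        seeded cohorts."""
        rng = np.random.default_rng(13)
        flagged = 0
        reps = 200
        for i in range(reps):
            ref = rng.lognormal(np.log(16), 0.9, size=45)
            dev = ref * rng.lognormal(-0.9, 0.5, size=45)
            groups = [(np.array([r]), np.array([d])) for r, d in zip(ref, dev)]
            res = analyze_agreement(groups, mode="summary", B=200, seed=i)
            flagged += (
                isinstance(res, ModeledBA)
                and res.transform == "log"
                and res.proportional_bias_detected
            )
        assert flagged / reps >= 0.90

    def test_modeled_loa_halfwidth_nonnegative_over_ref_range(self):
        rng = np.random.default_rng(14)
        groups = []
        for _ in range(6):
            ref = rng.uniform(20, 100, 200)
            dev = ref - (5 - 0.1 * ref) - rng.normal(0, 0.05 * ref)
            groups.append((ref, dev))
        res = analyze_agreement(groups, mode="epoch", B=200, seed=0)
        assert isinstance(res, ModeledBA)
        assert res.proportional_bias_detected
        assert (res.half_width_at(np.linspace(20, 100, 50)) >= 0).all()

    def test_gate_pvalues_are_retained(self):
        rng = np.random.default_rng(15)
        groups = []
        for _ in range(5):
            ref = rng.uniform(55, 75, 200)
            groups.append((ref, ref - rng.normal(0, 1, 200)))
        res = analyze_agreement(groups, mode="epoch", B=200, seed=0)
        assert "shapiro_p" in res.gates
        assert "proportional_bias_p" in res.gates
        assert "heteroscedasticity_p" in res.gates


def test_bias_recoverable_from_printed_loa():
    """Symmetric LOA construction: bias is the midpoint of the limits."""
    assert bias_from_loa(-1.96, 1.96) == 0.0
    assert bias_from_loa(3.0, 3.0) == 3.0
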