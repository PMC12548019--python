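"""Inversion: median estimates, confidence intervals, compatibility."""

import math

import numpy as np
import pytest
from scipy import stats

from pvalfn import (
    METHODS,
    CombinationMethod,
    CombinedInference,
    EstimationRequest,
    PValueFunctionSpec,
    TrialResult,
    ValidationError,
    centrality,
    confidence_interval,
    estimation_function,
    full_inference,
    get_fixture,
    implicit_weight,
    inference_table,
    median_estimate,
)


def spec_for(trials, method, alternative="greater", r=None):
    return PValueFunctionSpec(
        tuple(trials), CombinationMethod.parse(method, r), alternative
    )


def identical_trials(theta=0.0, sigma=1.0):
    return (TrialResult("a", theta, sigma), TrialResult("b", theta, sigma))


class TestClosedFormAnchors:
    """Identical-trials shifts and quantiles, in units of sigma."""

    def test_max_rule_median_shift(self):
        # median sits z at sqrt(1/2) ~ 0.54 standard errors above the
        # common estimate (alternative greater)
        spec = spec_for(identical_trials(), "two_trials_rule")
        shift = median_estimate(spec)
        assert shift == pytest.approx(stats.norm.ppf(math.sqrt(0.5)), abs=1e-10)
        assert round(shift, 2) == 0.54

    def test_max_rule_ci_quantiles(self):
        # the published annotations for the equal-trials 95% CI are -1 and 2.24
        lo, hi = confidence_interval(spec_for(identical_trials(), "two_trials_rule"))
        assert lo == pytest.approx(stats.norm.ppf(math.sqrt(0.025)), abs=1e-9)
        assert hi == pytest.approx(stats.norm.ppf(math.sqrt(0.975)), abs=1e-9)
        assert round(lo, 2) == -1.00
        assert round(hi, 2) == 2.24

    def test_min_rule_mirrors_max_rule(self):
        spec = spec_for(identical_trials(), "tippett")
        assert median_estimate(spec) == pytest.approx(
            -stats.norm.ppf(math.sqrt(0.5)), abs=1e-10
        )

    def test_product_rule_median_shift(self):
        # Fisher's median for identical trials is offset by the normal
        # quantile at exp(-chi2_4 median / 4) ~ -0.17 sigma
        shift = median_estimate(spec_for(identical_trials(), "fisher"))
        expected = stats.norm.ppf(math.exp(-stats.chi2.ppf(0.5, 4) / 4))
        assert shift == pytest.approx(expected, abs=1e-10)
        assert round(shift, 2) == -0.17
        # Pearson mirrors it
        assert median_estimate(spec_for(identical_trials(), "pearson")) == (
            pytest.approx(-shift, abs=1e-10)
        )

    def test_sum_rule_symmetric_ci(self):
        lo, hi = confidence_interval(spec_for(identical_trials(), "edgington"))
        assert lo == pytest.approx(-hi, abs=1e-10)
        assert hi == pytest.approx(-stats.norm.ppf(math.sqrt(0.025 / 2)), abs=1e-9)
        assert hi == pytest.approx(1.2170, abs=5e-5)

    def test_sum_rule_ci_narrower_than_pooled(self):
        # 12.2% narrower than the meta-analytic CI for identical trials
        lo_e, hi_e = confidence_interval(spec_for(identical_trials(), "edgington"))
        lo_m, hi_m = confidence_interval(spec_for(identical_trials(), "meta_analysis"))
        narrowing = 100 * (1 - (hi_e - lo_e) / (hi_m - lo_m))
        assert round(narrowing, 1) == 12.2

    def test_pooled_median_is_inverse_variance_mean(self):
        trials = (TrialResult("a", 0.2, 0.5), TrialResult("b", -0.1, 0.3))
        w = np.array([1 / 0.5**2, 1 / 0.3**2])
        expected = np.sum(w * np.array([0.2, -0.1])) / np.sum(w)
        assert median_estimate(spec_for(trials, "meta_analysis")) == pytest.approx(
            expected, abs=1e-12
        )

    def test_sum_rule_median_is_inverse_se_mean(self):
        trials = (TrialResult("a", 0.2, 0.5), TrialResult("b", -0.1, 0.3))
        w = np.array([1 / 0.5, 1 / 0.3])
        expected = np.sum(w * np.array([0.2, -0.1])) / np.sum(w)
        closed = median_estimate(spec_for(trials, "edgington"))
        assert closed == pytest.approx(expected, abs=1e-12)
        # cross-checked against numeric inversion of the sum combiner
        numeric = estimation_function(
            spec_for(trials, "edgington"), 0.5, force_numeric=True
        )
        assert closed == pytest.approx(numeric, abs=1e-9)


class TestClosedVersusNumeric:
    A_GRID = (0.000625, 0.0125, 0.025, 0.2, 0.5, 0.8, 0.975, 0.99)

    @pytest.mark.parametrize("method", ["two_trials_rule", "meta_analysis", "tippett"])
    @pytest.mark.parametrize("alternative", ["greater", "less"])
    def test_general_two_trials(self, method, alternative):
        trials = (TrialResult("a", -0.49, 0.18368), TrialResult("b", -0.18, 0.17602))
        spec = spec_for(trials, method, alternative)
        tol = 1e-8 * max(t.se for t in trials)
        for a in self.A_GRID:
            closed = estimation_function(spec, a)
            numeric = estimation_function(spec, a, force_numeric=True)
            assert abs(closed - numeric) <= tol

    @pytest.mark.parametrize("method", ["fisher", "pearson", "edgington"])
    def test_identical_trials_special_case(self, method):
        spec = spec_for(identical_trials(theta=-0.3, sigma=0.4), method)
        tol = 1e-8 * 0.4
        for a in self.A_GRID:
            closed = estimation_function(spec, a)
            numeric = estimation_function(spec, a, force_numeric=True)
            assert abs(closed - numeric) <= tol

    @pytest.mark.parametrize("k", [3, 4])
    def test_k_trial_closed_forms(self, k):
        rng = np.random.default_rng(5)
        trials = tuple(
            TrialResult(f"t{i}", rng.normal(), rng.uniform(0.2, 0.6))
            for i in range(k)
        )
        for method in ("two_trials_rule", "tippett", "meta_analysis"):
            spec = spec_for(trials, method)
            for a in (0.025, 0.5, 0.975):
                closed = estimation_function(spec, a)
                numeric = estimation_function(spec, a, force_numeric=True)
                assert abs(closed - numeric) <= 1e-8 * max(t.se for t in trials)

    def test_inversion_defines_the_p_value(self):
        """mu_hat(a) really solves p(mu) = a for the numeric-only methods."""
        fx = get_fixture("respire_14d")
        for method in METHODS:
            spec = spec_for(fx.trials, method, fx.alternative)
            for a in (0.025, 0.3, 0.5, 0.9):
                mu = estimation_function(spec, a)
                assert spec.p(mu) == pytest.approx(a, abs=1e-9)


PRINTED_TABLES = {
    # method -> (estimate, weight trial 1, ci lower, ci upper, ci width)
    "respire_14d": {
        "two_trials_rule": (-0.28, 0.31, -0.57, -0.01, 0.56),
        "meta_analysis": (-0.33, 0.47, -0.58, -0.08, 0.49),
        "tippett": (-0.39, 0.68, -0.68, -0.08, 0.59),
        "fisher": (-0.35, 0.55, -0.64, -0.09, 0.55),
        "pearson": (-0.32, 0.43, -0.58, -0.04, 0.53),
        "edgington": (-0.34, 0.49, -0.64, -0.05, 0.59),
    },
    "respire_28d": {
        "two_trials_rule": (-0.12, 0.82, -0.44, 0.17, 0.61),
        "meta_analysis": (-0.31, 0.50, -0.57, -0.05, 0.52),
        "tippett": (-0.50, 0.18, -0.79, -0.18, 0.60),
        "fisher": (-0.44, 0.28, -0.75, -0.12, 0.62),
        "pearson": (-0.18, 0.72, -0.50, 0.13, 0.62),
        "edgington": (-0.31, 0.50, -0.74, 0.12, 0.86),
    },
    "orbit_primary": {
        "two_trials_rule": (-0.10, 0.71, -0.39, 0.16, 0.55),
        "meta_analysis": (-0.18, 0.45, -0.41, 0.04, 0.45),
        "tippett": (-0.24, 0.26, -0.48, 0.02, 0.50),
        "fisher": (-0.21, 0.39, -0.45, 0.03, 0.49),
        "pearson": (-0.15, 0.57, -0.40, 0.12, 0.52),
        "edgington": (-0.18, 0.48, -0.45, 0.12, 0.57),
    },
    "orbit_secondary": {
        "two_trials_rule": (-0.24, 0.75, -0.47, -0.02, 0.45),
        "meta_analysis": (-0.31, 0.49, -0.51, -0.12, 0.38),
        "tippett": (-0.39, 0.25, -0.60, -0.16, 0.44),
        "fisher": (-0.35, 0.38, -0.57, -0.14, 0.43),
        "pearson": (-0.28, 0.62, -0.49, -0.05, 0.44),
        "edgington": (-0.31, 0.50, -0.57, -0.06, 0.51),
    },
}

# the published inputs (estimates and CI bounds) are rounded to 2 dp, so the
# reconstructed standard errors carry that rounding into every derived
# quantity; agreement is asserted at 2-decimal precision with an allowance of
# about one unit in the second decimal (CI widths compound two bounds)
TOL_POINT = 0.011
TOL_WIDTH = 0.016


@pytest.mark.parametrize("fixture_name", sorted(PRINTED_TABLES))
def test_reproduces_published_tables(fixture_name):
    fx = get_fixture(fixture_name)
    table = inference_table(fx.trials, METHODS, fx.alternative).set_index("method")
    for method, (est, w1, lo, hi, width) in PRINTED_TABLES[fixture_name].items():
        row = table.loc[method]
        assert row.estimate == pytest.approx(est, abs=TOL_POINT), method
        assert row.weight_trial1 == pytest.approx(w1, abs=TOL_POINT), method
        assert row.ci_lower == pytest.approx(lo, abs=TOL_POINT), method
        assert row.ci_upper == pytest.approx(hi, abs=TOL_POINT), method
        assert row.ci_width == pytest.approx(width, abs=TOL_WIDTH), method


def test_published_combined_p_at_null_from_printed_pvalues():
    fx = get_fixture("orbit_primary")
    table = inference_table(
        fx.trials, METHODS, fx.alternative, printed_pvalues=fx.printed_pvalues
    ).set_index("method")
    assert table.loc["two_trials_rule"].p_onesided == pytest.approx(0.22692, abs=1e-5)
    fx2 = get_fixture("orbit_secondary")
    table2 = inference_table(
        fx2.trials, METHODS, fx2.alternative, printed_pvalues=fx2.printed_pvalues
    ).set_index("method")
    assert table2.loc["two_trials_rule"].p_onesided == pytest.approx(0.01460, abs=1e-5)


class TestImplicitWeights:
    def test_weighted_average_decomposition(self):
        fx = get_fixture("respire_14d")
        for method in METHODS:
            spec = spec_for(fx.trials, method, fx.alternative)
            w = implicit_weight(spec)
            median = median_estimate(spec)
            theta1, theta2 = (t.estimate for t in fx.trials)
            assert w * theta1 + (1 - w) * theta2 == pytest.approx(median, abs=1e-10)

    def test_pooled_weight_is_analytic(self):
        trials = (TrialResult("a", 0.4, 0.5), TrialResult("b", -0.2, 0.3))
        w = implicit_weight(spec_for(trials, "meta_analysis"))
        assert w == pytest.approx(0.3**2 / (0.5**2 + 0.3**2), abs=1e-12)
        w_e = implicit_weight(spec_for(trials, "edgington"))
        assert w_e == pytest.approx(0.3 / (0.5 + 0.3), abs=1e-12)

    def test_undefined_for_identical_estimates(self):
        with pytest.raises(ValidationError):
            implicit_weight(spec_for(identical_trials(), "fisher"))


class TestCompatibility:
    """The headline property: test decisions and CIs always agree."""

    ALPHAS = (0.001, 0.00125, 0.01, 0.05, 0.1, 0.2)

    @pytest.mark.parametrize("fixture_name", ["respire_14d", "orbit_secondary"])
    @pytest.mark.parametrize("method", METHODS)
    def test_two_sided_p_below_alpha_iff_null_outside_ci(self, fixture_name, method):
        fx = get_fixture(fixture_name)
        spec = spec_for(fx.trials, method, fx.alternative)
        for alpha in self.ALPHAS:
            lo, hi = confidence_interval(spec, 1 - alpha)
            for mu0 in (-0.8, -0.4, -0.05, 0.0, 0.25):
                rejected = centrality(spec.p(mu0)) < alpha
                outside = not (lo <= mu0 <= hi)
                assert rejected == outside, (method, alpha, mu0)

    @pytest.mark.parametrize("method", METHODS)
    def test_median_inside_every_ci_and_cis_nested(self, method):
        fx = get_fixture("respire_28d")
        spec = spec_for(fx.trials, method, fx.alternative)
        request = EstimationRequest(spec, (0.5, 0.8, 0.95, 0.99875))
        result = full_inference(request)  # invariants checked on construction
        assert isinstance(result, CombinedInference)
        assert result.ci(0.95)[0] <= result.median_estimate <= result.ci(0.95)[1]


class TestOrientationAndDuality:
    def test_sum_rule_ci_is_orientation_invariant(self):
        fx = get_fixture("respire_14d")
        ci_less = confidence_interval(spec_for(fx.trials, "edgington", "less"))
        ci_greater = confidence_interval(spec_for(fx.trials, "edgington", "greater"))
        assert ci_less[0] == pytest.approx(ci_greater[0], abs=1e-9)
        assert ci_less[1] == pytest.approx(ci_greater[1], abs=1e-9)

    def test_max_rule_ci_is_not_orientation_invariant(self):
        fx = get_fixture("respire_14d")
        ci_less = confidence_interval(spec_for(fx.trials, "two_trials_rule", "less"))
        ci_greater = confidence_interval(
            spec_for(fx.trials, "two_trials_rule", "greater")
        )
        assert abs(ci_less[0] - ci_greater[0]) > 1e-3

    def test_same_median_under_opposite_alternatives(self):
        fx = get_fixture("respire_14d")
        med_max_g = median_estimate(spec_for(fx.trials, "two_trials_rule", "greater"))
        med_min_l = median_estimate(spec_for(fx.trials, "tippett", "less"))
        assert med_max_g == pytest.approx(med_min_l, abs=1e-12)


class TestAsymptoticLimits:
    """Shrinking both standard errors drives each method to its estimand."""

    THETA = (0.0, 1.0)
    SIGMA = (0.4, 0.3)

    def scaled(self, t):
        return (
            TrialResult("a", self.THETA[0], t * self.SIGMA[0]),
            TrialResult("b", self.THETA[1], t * self.SIGMA[1]),
        )

    @pytest.mark.parametrize(
        "method, target",
        [
            ("two_trials_rule", 0.0),  # less extreme (greater)
            ("pearson", 0.0),
            ("tippett", 1.0),  # more extreme
            ("fisher", 1.0),
        ],
    )
    def test_extreme_effect_targets(self, method, target):
        errors = []
        for t in (1.0, 0.1, 0.01):
            spec = spec_for(self.scaled(t), method, "greater")
            errors.append(abs(median_estimate(spec) - target))
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 0.02

    def test_weighted_average_targets(self):
        c = self.SIGMA[0] ** 2 / self.SIGMA[1] ** 2
        ma_target = self.THETA[0] / (1 + c) + self.THETA[1] / (1 + 1 / c)
        e_target = self.THETA[0] / (1 + math.sqrt(c)) + self.THETA[1] / (
            1 + 1 / math.sqrt(c)
        )
        for t in (1.0, 0.1, 0.01):
            spec_ma = spec_for(self.scaled(t), "meta_analysis", "greater")
            spec_e = spec_for(self.scaled(t), "edgington", "greater")
            assert median_estimate(spec_ma) == pytest.approx(ma_target, abs=1e-9)
            assert median_estimate(spec_e) == pytest.approx(e_target, abs=1e-9)

    def test_sum_rule_ci_keeps_both_effects(self):
        """The sum combiner's CI limits converge to min and max of the true
        effects: its width does not vanish under heterogeneity."""
        for t, tol in ((0.1, 0.1), (0.01, 0.01)):
            lo, hi = confidence_interval(spec_for(self.scaled(t), "edgington"), 0.95)
            assert lo == pytest.approx(min(self.THETA), abs=3 * tol)
            assert hi == pytest.approx(max(self.THETA), abs=3 * tol)
        assert hi - lo > 0.9  # no collapse

    def test_pooled_ci_collapses(self):
        lo, hi = confidence_interval(
            spec_for(self.scaled(0.01), "meta_analysis"), 0.95
        )
        assert hi - lo < 0.02


class TestRequestValidation:
    def test_levels_validated_sorted_deduplicated(self):
        fx = get_fixture("respire_14d")
        spec = spec_for(fx.trials, "fisher", fx.alternative)
        req = EstimationRequest(spec, (0.99, 0.95, 0.95))
        assert req.levels == (0.95, 0.99)
        with pytest.raises(ValidationError):
            EstimationRequest(spec, (1.5,))
        with pytest.raises(ValidationError):
            EstimationRequest(spec, ())
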