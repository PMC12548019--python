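"""Operating characteristics of combined median estimates.

Under the sampling model ``theta_hat_i | theta_i ~ N(theta_i, sigma_i^2)``
(independent trials), the median estimate of every combiner is median
unbiased when the true effects coincide, but the methods differ in mean
bias, sampling standard error, and in what they converge to when the true
effects differ.  This module provides the closed-form results that exist —

* the exact expectation of the two-trials-rule median for equal standard
  errors (expectation of a minimum of two normals plus a fixed quantile
  offset),
* sampling standard errors for the two-trials rule (equal effects and
  standard errors), meta-analysis and Edgington's method,
* the probability limit ("asymptotic target", the estimand) of each method
  as the standard errors shrink at fixed variance ratio —

plus a seeded Monte Carlo engine that verifies them and estimates coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (
    Alternative,
    CombinationMethod,
    TrialResult,
    ValidationError,
)
__all__ = [
    "OperatingCharacteristics",
    "SimulationScenario",
    "UnsupportedCaseError",
    "analytic_se",
    "asymptotic_target",
    "expected_median_2tr",
    "generate_random_pair",
    "simulate_oc",
]

#: z_{sqrt(1/2)} — offset (in standard errors) of the two-trials-rule median
#: from the smaller of two equal-precision estimates
Z_SQRT_HALF = float(stats.norm.ppf(math.sqrt(0.5)))


class UnsupportedCaseError(ValidationError):
    """A closed-form result was requested outside its derivation scope."""


def expected_median_2tr(theta1: float, theta2: float, sigma: float) -> float:
    """Exact expectation of the two-trials-rule median (equal standard errors,
    alternative "greater").

    The median is ``min(theta_hat_1, theta_hat_2) + sigma z_{sqrt(1/2)}``;
    taking the expectation of the minimum of two independent normals gives

    ``theta_1 Phi(d) + theta_2 Phi(-d) + sigma (z_{sqrt(1/2)} - sqrt(2) phi(d))``

    with ``d = (theta_2 - theta_1) / (sqrt(2) sigma)``.  For equal true
    effects this reduces to ``theta + sigma (z_{sqrt(1/2)} - 1/sqrt(pi))``,
    a conservative (negative) bias of about -0.019 sigma.  The unequal-sigma
    case has no closed form here (the expectation then depends on the true
    effects in a more complicated way): use :func:`simulate_oc`.
    """
    if not sigma > 0:
        raise ValidationError("sigma must be positive")
    d = (theta2 - theta1) / (math.sqrt(2.0) * sigma)
    return (
        theta1 * stats.norm.cdf(d)
        + theta2 * stats.norm.cdf(-d)
        + sigma * (Z_SQRT_HALF - math.sqrt(2.0) * stats.norm.pdf(d))
    )


def analytic_se(
    method: CombinationMethod | str,
    sigma1: float,
    sigma2: float | None = None,
) -> float:
    """Closed-form sampling standard error of the median estimate.

    * ``two_trials_rule``: ``sigma * sqrt(1 - 1/pi)`` (~ 0.83 sigma),
      derived only for equal true effects and equal standard errors — pass a
      single sigma; unequal sigmas raise :class:`UnsupportedCaseError`
      (use Monte Carlo).
    * ``meta_analysis``: ``1 / sqrt(1/sigma1^2 + 1/sigma2^2)``.
    * ``edgington``: ``sqrt(2) / (1/sigma1 + 1/sigma2)``; can exceed
      ``min(sigma1, sigma2)`` when the two standard errors are far apart.
    """
    method = CombinationMethod.parse(method)
    if not sigma1 > 0 or (sigma2 is not None and not sigma2 > 0):
        raise ValidationError("standard errors must be positive")
    if method.name == "two_trials_rule":
        if sigma2 is not None and sigma2 != sigma1:
            raise UnsupportedCaseError(
                "the two-trials-rule standard error is available in closed form "
                "only for equal true effects and equal standard errors; use "
                "simulate_oc for the general case"
            )
        return sigma1 * math.sqrt(1.0 - 1.0 / math.pi)
    if sigma2 is None:
        sigma2 = sigma1
    if method.name == "meta_analysis":
        return 1.0 / math.sqrt(1.0 / sigma1**2 + 1.0 / sigma2**2)
    if method.name == "edgington":
        return math.sqrt(2.0) / (1.0 / sigma1 + 1.0 / sigma2)
    raise UnsupportedCaseError(
        f"no closed-form median standard error for {method.name!r}; "
        "use simulate_oc"
    )


def weighted_average_target(theta1: float, theta2: float, c: float,
                            inverse_se: bool = False) -> float:
    """Limit of the weighted-average estimand at variance ratio
    ``c = sigma1^2/sigma2^2``: ``theta1/(1 + c) + theta2/(1 + 1/c)`` for
    meta-analysis (inverse-variance weights) and the same expression with
    ``sqrt(c)`` for Edgington (inverse-standard-error weights)."""
    if inverse_se:
        c = math.sqrt(c)
    return theta1 / (1.0 + c) + theta2 / (1.0 + 1.0 / c)


def asymptotic_target(
    method: CombinationMethod | str,
    theta1: float,
    theta2: float,
    c: float = 1.0,
    alternative: Alternative | str = Alternative.GREATER,
    a: float = 0.5,
):
    """Probability limit of ``mu_hat(a)`` as both standard errors shrink at
    fixed variance ratio ``c = sigma1^2 / sigma2^2``.

    Conservative methods (two-trials rule, Pearson) converge to the less
    extreme true effect, anti-conservative ones (Tippett, Fisher) to the
    more extreme, and the averaging methods to weighted means.  Edgington is
    special: its median targets the inverse-standard-error weighted average,
    but its CI limits converge to ``min(theta)`` (a < 1/2) and
    ``max(theta)`` (a > 1/2), so its CI never shrinks past the two true
    effects when they differ.
    """
    method = CombinationMethod.parse(method)
    alternative = Alternative.parse(alternative)
    greater = alternative is Alternative.GREATER
    lo, hi = min(theta1, theta2), max(theta1, theta2)
    name = method.name
    if name in ("two_trials_rule", "pearson"):
        return lo if greater else hi
    if name in ("tippett", "fisher"):
        return hi if greater else lo
    if name == "meta_analysis":
        return weighted_average_target(theta1, theta2, c)
    if name == "edgington":
        if a < 0.5:
            return lo
        if a > 0.5:
            return hi
        return weighted_average_target(theta1, theta2, c, inverse_se=True)
    raise UnsupportedCaseError(f"no asymptotic target implemented for {name!r}")


@dataclass(frozen=True)
class SimulationScenario:
    """True state of a simulated pair of trials plus the analysis settings."""

    theta1: float
    theta2: float
    sigma1: float
    sigma2: float
    method: CombinationMethod
    alternative: Alternative = Alternative.GREATER
    n_sim: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", CombinationMethod.parse(self.method))
        object.__setattr__(self, "alternative", Alternative.parse(self.alternative))
        if not (self.sigma1 > 0 and self.sigma2 > 0):
            raise ValidationError("true standard errors must be positive")
        if self.n_sim < 100:
            raise ValidationError("n_sim must be at least 100")

    @property
    def variance_ratio(self) -> float:
        """c = sigma1^2 / sigma2^2."""
        return self.sigma1**2 / self.sigma2**2

    @property
    def homogeneous(self) -> bool:
        return self.theta1 == self.theta2


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Monte Carlo (or analytic) summaries of a median estimate's sampling
    distribution.  ``coverage`` maps CI level -> empirical coverage of the
    target; ``target`` is the covered quantity (the common true effect under
    homogeneity, otherwise the method's own estimand)."""

    mean_of_median: float
    bias: float
    se_of_median: float
    target: float
    coverage: dict
    mc_standard_error: float
    coverage_mc_se: dict
    n_sim: int


def generate_random_pair(
    theta1: float,
    theta2: float,
    sigma1: float,
    sigma2: float,
    seed: int | np.random.Generator,
) -> tuple[TrialResult, TrialResult]:
    """Draw one simulated pair of trial results,
    ``theta_hat_i ~ N(theta_i, sigma_i^2)`` independently; reproducible for
    a fixed seed."""
    if not (sigma1 > 0 and sigma2 > 0):
        raise ValidationError("standard errors must be positive")
    rng = np.random.default_rng(seed)
    est1 = rng.normal(theta1, sigma1)
    est2 = rng.normal(theta2, sigma2)
    return (
        TrialResult("sim_1", float(est1), float(sigma1)),
        TrialResult("sim_2", float(est2), float(sigma2)),
    )


# -- vectorized two-trial inversion (Monte Carlo fast path) ------------------
#
# The Monte Carlo engine inverts the combined p-value function once per
# replicate, so it uses array-valued closed forms where they exist and a
# vectorized bisection on the monotone combined p function otherwise.  The
# scalar path in :mod:`pvalfn.estimation` is the reference implementation;
# agreement between the two is asserted by tests.


def _combined_p_two_vec(name, est1, est2, s1, s2, mu, greater: bool):
    """Combined p for two trials, vectorized over replicates (k = 2 only)."""
    z1 = (est1 - mu) / s1
    z2 = (est2 - mu) / s2
    if greater:
        p1, p2 = stats.norm.sf(z1), stats.norm.sf(z2)
    else:
        p1, p2 = stats.norm.cdf(z1), stats.norm.cdf(z2)
    if name == "two_trials_rule":
        return np.maximum(p1, p2) ** 2
    if name == "tippett":
        return 1.0 - (1.0 - np.minimum(p1, p2)) ** 2
    if name == "fisher":
        c = np.clip(p1 * p2, 1e-300, None)
        return stats.chi2.sf(-2.0 * np.log(c), df=4)
    if name == "pearson":
        c = np.clip((1.0 - p1) * (1.0 - p2), 1e-300, None)
        return stats.chi2.cdf(-2.0 * np.log(c), df=4)
    if name == "edgington":
        e = p1 + p2
        return np.where(e <= 1.0, e**2 / 2.0, 1.0 - (2.0 - e) ** 2 / 2.0)
    if name == "meta_analysis":
        w1, w2 = 1.0 / s1, 1.0 / s2
        zc = (w1 * (z1 if greater else -z1) + w2 * (z2 if greater else -z2)) / (
            math.sqrt(w1**2 + w2**2)
        )
        return stats.norm.sf(zc)
    raise UnsupportedCaseError(f"no vectorized combiner for {name!r}")


def _mu_hat_many(name, est1, est2, s1, s2, a: float, greater: bool) -> np.ndarray:
    """Array-valued mu_hat(a) for two trials with common sigmas s1, s2."""
    if name == "two_trials_rule":
        q = float(stats.norm.ppf(math.sqrt(a)))
        vals = (est1 + s1 * q, est2 + s2 * q) if greater else (est1 - s1 * q, est2 - s2 * q)
        return np.minimum(*vals) if greater else np.maximum(*vals)
    if name == "tippett":
        q = float(stats.norm.ppf(math.sqrt(1.0 - a)))
        vals = (est1 - s1 * q, est2 - s2 * q) if greater else (est1 + s1 * q, est2 + s2 * q)
        return np.maximum(*vals) if greater else np.minimum(*vals)
    if name == "meta_analysis":
        w1, w2 = 1.0 / s1**2, 1.0 / s2**2
        theta_ma = (w1 * est1 + w2 * est2) / (w1 + w2)
        sigma_ma = 1.0 / math.sqrt(w1 + w2)
        za = float(stats.norm.ppf(a))
        return theta_ma + sigma_ma * za if greater else theta_ma - sigma_ma * za
    if name == "edgington" and a == 0.5:
        w1, w2 = 1.0 / s1, 1.0 / s2
        return (w1 * est1 + w2 * est2) / (w1 + w2)
    # vectorized bisection on the monotone combined p function
    lo = np.minimum(est1, est2) - 12.0 * max(s1, s2)
    hi = np.maximum(est1, est2) + 12.0 * max(s1, s2)
    for _ in range(90):
        mid = 0.5 * (lo + hi)
        too_low = _combined_p_two_vec(name, est1, est2, s1, s2, mid, greater) < a
        if not greater:  # p decreasing in mu: flip the update direction
            too_low = ~too_low
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


def simulate_oc(
    scenario: SimulationScenario,
    levels: tuple[float, ...] = (0.95,),
) -> OperatingCharacteristics:
    """Monte Carlo operating characteristics of the median estimate.

    Draws ``n_sim`` trial pairs from the scenario, computes the median
    estimate and CIs for each, and reports the mean, bias and empirical
    standard error of the median plus CI coverage, all with Monte Carlo
    standard errors.  Coverage is evaluated at the common true effect under
    homogeneity and at the method's asymptotic target (its estimand) under
    heterogeneity.
    """
    rng = np.random.default_rng(scenario.seed)
    est1 = rng.normal(scenario.theta1, scenario.sigma1, scenario.n_sim)
    est2 = rng.normal(scenario.theta2, scenario.sigma2, scenario.n_sim)

    target = (
        scenario.theta1
        if scenario.homogeneous
        else asymptotic_target(
            scenario.method,
            scenario.theta1,
            scenario.theta2,
            scenario.variance_ratio,
            scenario.alternative,
        )
    )

    name = scenario.method.name
    greater = scenario.alternative is Alternative.GREATER
    s1, s2 = scenario.sigma1, scenario.sigma2
    medians = _mu_hat_many(name, est1, est2, s1, s2, 0.5, greater)
    coverage = {}
    coverage_mc_se = {}
    n = scenario.n_sim
    for level in levels:
        alpha = 1.0 - level
        b1 = _mu_hat_many(name, est1, est2, s1, s2, alpha / 2.0, greater)
        b2 = _mu_hat_many(name, est1, est2, s1, s2, 1.0 - alpha / 2.0, greater)
        lower, upper = np.minimum(b1, b2), np.maximum(b1, b2)
        cov = float(np.mean((lower <= target) & (target <= upper)))
        coverage[level] = cov
        coverage_mc_se[level] = math.sqrt(max(cov * (1.0 - cov), 1e-12) / n)

    mean = float(np.mean(medians))
    se = float(np.std(medians, ddof=1))
    return OperatingCharacteristics(
        mean_of_median=mean,
        bias=mean - target,
        se_of_median=se,
        target=target,
        coverage=coverage,
        coverage_mc_se=coverage_mc_se,
        mc_standard_error=se / math.sqrt(n),
        n_sim=n,
    )
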