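"""Inversion of combined p-value functions into estimates and intervals.

The combined estimation function ``mu_hat(a) = {mu : p(mu) = a}`` is the
inverse of the combined p-value function.  Setting a = 1/2 yields the median
estimate; a = alpha/2 and a = 1 - alpha/2 yield the limits of a two-sided
(1 - alpha) confidence interval.  Because every combiner here is continuous
and strictly monotone in mu, the inverse exists and is unique, and the
resulting p-values, median estimates and confidence intervals are mutually
compatible: the two-sided p-value at a null value falls below alpha exactly
when the (1 - alpha) CI excludes it, and the median estimate lies inside
every CI.

Closed forms are used where they exist:

* two-trials rule / Wilkinson(r = k):  ``min_i {theta_i + sigma_i z_{a^(1/k)}}``
  (alternative "greater"; mirrored for "less"),
* Tippett / Wilkinson(r = 1):  ``max_i {theta_i - sigma_i z_{(1-a)^(1/k)}}``,
* meta-analysis:  ``theta_MA + sigma_MA z_a``,
* Edgington median (two trials only): inverse-standard-error weighted mean,
* Fisher / Pearson / Edgington with identical trials: normal quantiles at
  transformed levels (see the functions below).

Everything else is inverted by bracketed Brent root-finding on the monotone
combined p-value function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import (
    Alternative,
    CombinationMethod,
    ProbabilityLevel,
    ValidationError,
)
from .combine import PValueFunctionSpec, centrality, combine_pvalues

__all__ = [
    "CombinedInference",
    "EstimationRequest",
    "confidence_interval",
    "estimation_function",
    "full_inference",
    "implicit_weight",
    "inference_table",
]

#: default confidence levels: conventional 95% plus the regulatory
#: 1 - 2 * 0.025^2 = 99.875% level that aligns two-sided CIs with the
#: one-sided alpha^2 = 0.000625 decision threshold
DEFAULT_LEVELS = (0.95, 0.99875)


def _z(q: float) -> float:
    return float(stats.norm.ppf(q))


def _identical_trials(spec: PValueFunctionSpec) -> bool:
    theta, sig = spec.estimates, spec.sigmas
    return bool(np.all(theta == theta[0]) and np.all(sig == sig[0]))


def _closed_form(spec: PValueFunctionSpec, a: float) -> float | None:
    """Closed-form mu_hat(a) where available, else None."""
    theta, sig, k = spec.estimates, spec.sigmas, spec.k
    greater = spec.alternative is Alternative.GREATER
    name = spec.method.name
    if name == "wilkinson" and spec.method.wilkinson_r == k:
        name = "two_trials_rule"
    if name == "wilkinson" and spec.method.wilkinson_r == 1:
        name = "tippett"

    if name == "two_trials_rule":
        # max p_i = a^(1/k); each trial solved at the k-th root level
        q = _z(a ** (1.0 / k))
        vals = theta + sig * q if greater else theta - sig * q
        return float(np.min(vals) if greater else np.max(vals))
    if name == "tippett":
        # min p_i = 1 - (1-a)^(1/k)
        q = _z((1.0 - a) ** (1.0 / k))
        vals = theta - sig * q if greater else theta + sig * q
        return float(np.max(vals) if greater else np.min(vals))
    if name == "meta_analysis":
        w = 1.0 / sig**2
        theta_ma = float(np.sum(w * theta) / np.sum(w))
        sigma_ma = float(1.0 / math.sqrt(np.sum(w)))
        return theta_ma + sigma_ma * _z(a) if greater else theta_ma - sigma_ma * _z(a)
    if name == "edgington" and k == 2 and a == 0.5:
        # inverse-standard-error weighted mean; two trials only
        w = 1.0 / sig
        return float(np.sum(w * theta) / np.sum(w))
    if name == "edgington" and _identical_trials(spec) and k == 2:
        q = _z(math.sqrt(a / 2.0)) if a <= 0.5 else -_z(math.sqrt((1.0 - a) / 2.0))
        shift = sig[0] * q
        return float(theta[0] + shift if greater else theta[0] - shift)
    if name in ("fisher", "pearson") and _identical_trials(spec) and k == 2:
        if name == "fisher":
            q = _z(math.exp(-stats.chi2.ppf(1.0 - a, df=4) / 4.0))
            shift = sig[0] * q
        else:
            q = _z(math.exp(-stats.chi2.ppf(a, df=4) / 4.0))
            shift = -sig[0] * q
        return float(theta[0] + shift if greater else theta[0] - shift)
    return None


#: relative p-tolerance for declaring the root converged
_P_TOL = 1e-12
_MAX_BRACKET_DOUBLINGS = 60


def _numeric_inverse(spec: PValueFunctionSpec, a: float) -> float:
    """Bracketed Brent root-finding on the monotone combined p function."""
    theta, sig = spec.estimates, spec.sigmas
    lo = float(np.min(theta) - 10.0 * np.max(sig))
    hi = float(np.max(theta) + 10.0 * np.max(sig))

    def f(mu: float) -> float:
        return spec.p(mu) - a

    f_lo, f_hi = f(lo), f(hi)
    width = hi - lo
    for _ in range(_MAX_BRACKET_DOUBLINGS):
        if f_lo == 0.0:
            return lo
        if f_hi == 0.0:
            return hi
        if f_lo * f_hi < 0.0:
            break
        width *= 2.0
        lo -= width
        hi += width
        f_lo, f_hi = f(lo), f(hi)
    else:
        raise ValidationError(
            f"could not bracket the root of p(mu) = {a} for method "
            f"{spec.method.name!r}"
        )
    xtol = 1e-12 * max(float(np.max(sig)), 1.0)
    return float(optimize.brentq(f, lo, hi, xtol=xtol, rtol=8.9e-16))


def estimation_function(
    spec: PValueFunctionSpec, a: float, force_numeric: bool = False
) -> float:
    """The null value mu at which the combined p-value function equals ``a``.

    Routes to the closed form where one exists (unless ``force_numeric``)
    and to monotone bracketed root-finding otherwise.
    """
    a = ProbabilityLevel(float(a)).a
    if not force_numeric:
        mu = _closed_form(spec, a)
        if mu is not None:
            return mu
    return _numeric_inverse(spec, a)


def median_estimate(spec: PValueFunctionSpec) -> float:
    """Median estimate: the null value where the p-value function is 1/2."""
    return estimation_function(spec, 0.5)


def confidence_interval(
    spec: PValueFunctionSpec, level: float = 0.95
) -> tuple[float, float]:
    """Two-sided (level x 100)% CI from the combined p-value function.

    The limits are ``mu_hat(alpha/2)`` and ``mu_hat(1 - alpha/2)`` with
    ``alpha = 1 - level``; returned sorted so that the lower bound comes
    first for either alternative.
    """
    level = ProbabilityLevel(float(level)).a
    alpha = 1.0 - level
    bounds = sorted(
        (
            estimation_function(spec, alpha / 2.0),
            estimation_function(spec, 1.0 - alpha / 2.0),
        )
    )
    return bounds[0], bounds[1]


def implicit_weight(spec: PValueFunctionSpec, median: float | None = None) -> float:
    """Weight of the first trial's estimate in the median estimate.

    For two trials the median can be written ``w * theta_1 + (1 - w) *
    theta_2``; this returns ``w = (median - theta_2)/(theta_1 - theta_2)``.
    Conservative combiners put more weight on the less extreme trial,
    anti-conservative ones on the more extreme trial; the weight may fall
    outside [0, 1] when the median lies outside the estimate range.
    """
    if spec.k != 2:
        raise ValidationError("implicit weights are defined for two trials only")
    theta1, theta2 = spec.estimates
    if theta1 == theta2:
        raise ValidationError(
            "implicit weight undefined for identical estimates (theta_1 = theta_2)"
        )
    if median is None:
        median = median_estimate(spec)
    return float((median - theta2) / (theta1 - theta2))


@dataclass(frozen=True)
class EstimationRequest:
    """What to compute: a p-value function plus confidence levels and the
    null value at which to report the combined p-value."""

    spec: PValueFunctionSpec
    levels: tuple[float, ...] = DEFAULT_LEVELS
    null_value: float = 0.0

    def __post_init__(self) -> None:
        levels = tuple(sorted({ProbabilityLevel(float(l)).a for l in self.levels}))
        if not levels:
            raise ValidationError("at least one confidence level is required")
        object.__setattr__(self, "levels", levels)


@dataclass(frozen=True)
class CombinedInference:
    """Result bundle: median estimate, CIs, combined p, implicit weights."""

    method: CombinationMethod
    alternative: Alternative
    median_estimate: float
    cis: tuple[tuple[float, float, float], ...]  # (level, lower, upper)
    p_at_null: float
    null_value: float
    implicit_weights: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for level, lower, upper in self.cis:
            if not lower <= self.median_estimate <= upper:
                raise ValidationError(
                    f"median estimate {self.median_estimate:.6g} outside the "
                    f"{level:.6g} CI ({lower:.6g}, {upper:.6g})"
                )
        by_level = sorted(self.cis)
        for (l1, lo1, up1), (l2, lo2, up2) in zip(by_level, by_level[1:]):
            if not (lo2 <= lo1 and up1 <= up2):
                raise ValidationError(
                    f"CIs not nested between levels {l1} and {l2}"
                )

    def ci(self, level: float) -> tuple[float, float]:
        for lvl, lower, upper in self.cis:
            if math.isclose(lvl, level):
                return lower, upper
        raise KeyError(f"no CI at level {level}")

    @property
    def p_twosided_at_null(self) -> float:
        return centrality(self.p_at_null)


def full_inference(request: EstimationRequest) -> CombinedInference:
    """Median estimate, CIs at all requested levels, p at the null value and
    (two trials) implicit weights, all from one combined p-value function."""
    spec = request.spec
    median = median_estimate(spec)
    cis = tuple(
        (level, *confidence_interval(spec, level)) for level in request.levels
    )
    p_null = spec.p(request.null_value)
    weights = None
    if spec.k == 2 and spec.estimates[0] != spec.estimates[1]:
        w1 = implicit_weight(spec, median)
        weights = (w1, 1.0 - w1)
    return CombinedInference(
        method=spec.method,
        alternative=spec.alternative,
        median_estimate=median,
        cis=cis,
        p_at_null=p_null,
        null_value=request.null_value,
        implicit_weights=weights,
    )


def inference_table(
    trials,
    methods,
    alternative=Alternative.GREATER,
    levels=DEFAULT_LEVELS,
    null_value: float = 0.0,
    ci_level: float = 0.95,
    printed_pvalues=None,
) -> pd.DataFrame:
    """One row per method: estimate, weight of trial 1, CI, width, p.

    ``printed_pvalues``, if given, are per-trial one-sided p-values (e.g. as
    published) used for the combined p column instead of p-values implied by
    the reconstructed standard errors; this isolates the two rounding
    pathways when reproducing published tables.  Widths are computed from
    unrounded limits.
    """
    rows = []
    for method in methods:
        method = CombinationMethod.parse(method)
        spec = PValueFunctionSpec(tuple(trials), method, Alternative.parse(alternative))
        request = EstimationRequest(spec, tuple(levels), null_value)
        result = full_inference(request)
        lower, upper = result.ci(ci_level)
        if printed_pvalues is not None and method.name != "meta_analysis":
            p_null = combine_pvalues(printed_pvalues, method)
        elif printed_pvalues is not None:
            p_null = combine_pvalues(
                printed_pvalues, method, sigmas=spec.sigmas
            )
        else:
            p_null = result.p_at_null
        rows.append(
            {
                "method": method.name,
                "estimate": result.median_estimate,
                "weight_trial1": (
                    result.implicit_weights[0] if result.implicit_weights else np.nan
                ),
                "ci_lower": lower,
                "ci_upper": upper,
                "ci_width": upper - lower,
                "p_onesided": p_null,
            }
        )
    return pd.DataFrame(rows)
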