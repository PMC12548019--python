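"""Combined one-sided p-value functions.

Each of k trials contributes a one-sided p-value function
``p_i(mu) = 1 - Phi((theta_i - mu)/sigma_i)`` (alternative "greater") or its
mirror image (alternative "less").  A combiner g maps the k individual
p-values to a single combined p-value that is again uniform under the null,
so the combined function ``p(mu) = g(p_1(mu), ..., p_k(mu))`` is a valid
p-value function: monotone in mu, invertible into a median estimate and
confidence intervals.

Implemented combiners (two-trial special cases in parentheses):

========================  =====================================================
two_trials_rule           squared maximum, ``max(p)^k`` (Wilkinson r = k)
meta_analysis             inverse-variance weighted Stouffer z-combination
tippett                   minimum, ``1 - (1 - min(p))^k`` (Wilkinson r = 1)
fisher                    product, upper chi^2_{2k} tail of ``-2 sum log p``
pearson                   product of complements, lower chi^2_{2k} tail
edgington                 sum, Irwin-Hall CDF of order k
wilkinson                 r-th smallest p, binomial upper tail
========================  =====================================================
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    Alternative,
    CombinationMethod,
    TrialResult,
    ValidationError,
)

__all__ = [
    "PValueFunctionSpec",
    "centrality",
    "combine_pvalues",
    "combined_p",
    "curve_frame",
    "irwin_hall_cdf",
    "one_sided_p",
    "stouffer_z",
]

#: floor applied to p-values (and their complements) before taking logs
P_CLIP = 1e-300

#: largest Edgington order for which the exact Irwin-Hall alternating sum
#: is numerically trustworthy in double precision
IRWIN_HALL_MAX_K = 30


def one_sided_p(trial: TrialResult, mu, alternative=Alternative.GREATER):
    """One-sided p-value function of a single trial, evaluated at ``mu``.

    Returns ``1 - Phi((estimate - mu)/se)`` for alternative ``greater`` and
    ``Phi((estimate - mu)/se)`` for ``less``; vectorised over ``mu``.
    """
    alternative = Alternative.parse(alternative)
    z = (trial.estimate - np.asarray(mu, dtype=float)) / trial.se
    if alternative is Alternative.GREATER:
        return stats.norm.sf(z)
    return stats.norm.cdf(z)


def irwin_hall_cdf(x, k: int):
    """CDF of the sum of ``k`` independent Uniform(0, 1) variables.

    Uses the exact alternating sum
    ``F(x) = (1/k!) * sum_{j=0}^{floor(x)} (-1)^j C(k, j) (x - j)^k``
    with compensated (fsum) accumulation; the terms alternate in sign and
    grow with k, so naive summation loses digits.  Orders beyond
    ``IRWIN_HALL_MAX_K`` are refused rather than silently approximated.
    """
    if not (1 <= k <= IRWIN_HALL_MAX_K):
        raise ValidationError(
            f"Irwin-Hall order must be in [1, {IRWIN_HALL_MAX_K}], got {k}"
        )
    x_arr = np.asarray(x, dtype=float)
    out = np.empty(x_arr.shape, dtype=float)
    for idx, xi in np.ndenumerate(x_arr):
        if xi <= 0.0:
            out[idx] = 0.0
        elif xi >= k:
            out[idx] = 1.0
        else:
            terms = [
                (-1.0) ** j * math.comb(k, j) * (xi - j) ** k
                for j in range(int(math.floor(xi)) + 1)
            ]
            out[idx] = min(1.0, max(0.0, math.fsum(terms) / math.factorial(k)))
    return out if out.shape else float(out)


def _clip_p(p: np.ndarray, what: str) -> np.ndarray:
    if np.any(p < P_CLIP):
        warnings.warn(
            f"{what} below {P_CLIP:g} clipped before taking logs", stacklevel=3
        )
    return np.clip(p, P_CLIP, 1.0)


def combine_pvalues(
    pvalues,
    method: CombinationMethod | str,
    sigmas=None,
    wilkinson_r: int | None = None,
):
    """Combine k one-sided p-values directly into one combined p-value.

    This is the bare combiner g: it acts on already-computed p-values and is
    the entry point for reproducing combined p-values from published
    per-trial p-values.  ``sigmas`` (per-trial standard errors, used as
    inverse weights) is required only for ``meta_analysis``.

    ``pvalues`` may be a 1-D array of k p-values (returns a float) or a
    (k, n) matrix of n p-value tuples (returns an n-vector), combined along
    axis 0.
    """
    method = CombinationMethod.parse(method, wilkinson_r)
    p = np.asarray(pvalues, dtype=float)
    scalar_out = p.ndim == 1
    if scalar_out:
        p = p[:, None]
    if p.ndim != 2 or p.shape[0] < 2:
        raise ValidationError("need at least two p-values to combine")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    k = p.shape[0]

    name = method.name
    if name == "two_trials_rule":
        out = np.max(p, axis=0) ** k
    elif name == "wilkinson":
        r = method.wilkinson_r
        if r > k:
            raise ValidationError(f"wilkinson rank {r} exceeds number of trials {k}")
        p_r = np.sort(p, axis=0)[r - 1]
        # Pr(at least r of k uniforms <= p_(r))
        out = stats.binom.sf(r - 1, k, p_r)
    elif name == "tippett":
        pmin = np.min(p, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(pmin >= 1.0, 1.0, -np.expm1(k * np.log1p(-pmin)))
    elif name == "fisher":
        stat = -2.0 * np.sum(np.log(_clip_p(p, "p-values")), axis=0)
        out = stats.chi2.sf(stat, df=2 * k)
    elif name == "pearson":
        stat = -2.0 * np.sum(
            np.log(_clip_p(1.0 - p, "complements of p-values")), axis=0
        )
        out = stats.chi2.cdf(stat, df=2 * k)
    elif name == "edgington":
        out = np.asarray(irwin_hall_cdf(np.sum(p, axis=0), k))
    elif name == "meta_analysis":
        if sigmas is None:
            raise ValidationError(
                "meta_analysis needs per-trial standard errors (sigmas) as weights"
            )
        sig = np.asarray(sigmas, dtype=float)
        if sig.shape != (k,) or np.any(sig <= 0):
            raise ValidationError("sigmas must be positive, one per p-value")
        # z_i = Phi^{-1}(1 - p_i); clip keeps the quantile finite
        z = stats.norm.isf(np.clip(p, P_CLIP, 1.0 - 1e-16))
        w = (1.0 / sig)[:, None]
        z_comb = np.sum(w * z, axis=0) / math.sqrt(np.sum(w**2))
        out = stats.norm.sf(z_comb)
    else:  # pragma: no cover
        raise AssertionError(f"unhandled method {name}")
    return float(out[0]) if scalar_out else out


@dataclass(frozen=True)
class PValueFunctionSpec:
    """A combined p-value function: trials + combination method + alternative.

    Evaluable at any null value mu via :meth:`p` (one-sided) or
    :meth:`p_twosided` (centrality transform).
    """

    trials: tuple[TrialResult, ...]
    method: CombinationMethod
    alternative: Alternative = Alternative.GREATER

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))
        object.__setattr__(self, "method", CombinationMethod.parse(self.method))
        object.__setattr__(self, "alternative", Alternative.parse(self.alternative))
        k = len(self.trials)
        if k < 2:
            raise ValidationError("a combined p-value function needs >= 2 trials")
        if self.method.name == "wilkinson" and self.method.wilkinson_r > k:
            raise ValidationError(
                f"wilkinson rank {self.method.wilkinson_r} exceeds k = {k}"
            )
        if self.method.name == "edgington" and k > IRWIN_HALL_MAX_K:
            raise ValidationError(
                f"edgington supports at most k = {IRWIN_HALL_MAX_K} trials"
            )

    @property
    def k(self) -> int:
        return len(self.trials)

    @property
    def estimates(self) -> np.ndarray:
        return np.array([t.estimate for t in self.trials])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([t.se for t in self.trials])

    def individual_p(self, mu) -> np.ndarray:
        """Matrix of per-trial one-sided p-values, shape (k,) + shape(mu)."""
        return np.array([one_sided_p(t, mu, self.alternative) for t in self.trials])

    def _mirror(self) -> Alternative:
        return (
            Alternative.LESS
            if self.alternative is Alternative.GREATER
            else Alternative.GREATER
        )

    def p(self, mu):
        """Combined one-sided p-value function evaluated at ``mu``.

        Vectorised over ``mu``.  The complements 1 - p_i needed by
        Pearson's and Tippett's combiners are computed from the mirrored
        normal tail rather than by subtraction, so the function stays
        accurate far out in the tails.
        """
        mu_arr = np.asarray(mu, dtype=float)
        flat = np.atleast_1d(mu_arr).ravel()
        name = self.method.name
        k = self.k

        if name == "meta_analysis":
            # exact z-combination: Z_MA = (theta_MA - mu)/sigma_MA
            w = 1.0 / self.sigmas**2
            theta_ma = float(np.sum(w * self.estimates) / np.sum(w))
            sigma_ma = 1.0 / math.sqrt(np.sum(w))
            z = (theta_ma - flat) / sigma_ma
            out = (
                stats.norm.sf(z)
                if self.alternative is Alternative.GREATER
                else stats.norm.cdf(z)
            )
        elif name == "fisher":
            pmat = self.individual_p(flat)
            stat = -2.0 * np.sum(np.log(np.clip(pmat, P_CLIP, 1.0)), axis=0)
            out = stats.chi2.sf(stat, df=2 * k)
        elif name == "pearson":
            # 1 - p_i is the one-sided p under the mirrored alternative
            comp = np.array(
                [one_sided_p(t, flat, self._mirror()) for t in self.trials]
            )
            stat = -2.0 * np.sum(np.log(np.clip(comp, P_CLIP, 1.0)), axis=0)
            out = stats.chi2.cdf(stat, df=2 * k)
        elif name == "tippett":
            comp = np.array(
                [one_sided_p(t, flat, self._mirror()) for t in self.trials]
            )
            out = 1.0 - np.max(comp, axis=0) ** k
        elif name == "two_trials_rule":
            out = np.max(self.individual_p(flat), axis=0) ** k
        elif name == "wilkinson":
            r = self.method.wilkinson_r
            p_r = np.sort(self.individual_p(flat), axis=0)[r - 1]
            out = stats.binom.sf(r - 1, k, p_r)
        elif name == "edgington":
            out = irwin_hall_cdf(np.sum(self.individual_p(flat), axis=0), k)
        else:  # pragma: no cover
            raise AssertionError(f"unhandled method {name}")
        out = np.asarray(out, dtype=float)
        return float(out[0]) if mu_arr.ndim == 0 else out.reshape(mu_arr.shape)

    def p_twosided(self, mu):
        """Two-sided p-value function ``2 min(p, 1 - p)`` (centrality)."""
        return centrality(self.p(mu))


def combined_p(spec: PValueFunctionSpec, mu):
    """Functional alias for ``spec.p(mu)``."""
    return spec.p(mu)


def stouffer_z(trials, mu, alternative=Alternative.GREATER) -> float:
    """Weighted Stouffer z-statistic ``sum(Z_i/sigma_i)/sqrt(sum 1/sigma_i^2)``.

    Algebraically identical to ``(theta_MA - mu)/sigma_MA`` with the
    inverse-variance pooled estimate and standard error; oriented so that
    large values favour the stated alternative.
    """
    alternative = Alternative.parse(alternative)
    theta = np.array([t.estimate for t in trials])
    sig = np.array([t.se for t in trials])
    z = (theta - float(mu)) / sig
    if alternative is Alternative.LESS:
        z = -z
    return float(np.sum(z / sig) / math.sqrt(np.sum(1.0 / sig**2)))


def centrality(p):
    """Two-sided (centrality) transform ``2 min(p, 1 - p)`` of a one-sided
    p-value; equals 1 at p = 1/2 and peaks at the median estimate when
    applied along a p-value function."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValidationError("p must lie in [0, 1]")
    out = 2.0 * np.minimum(p_arr, 1.0 - p_arr)
    return float(out) if p_arr.ndim == 0 else out


def default_mu_grid(trials, n: int = 1001) -> np.ndarray:
    """Null-value grid spanning median(estimates) ± 5 max(se) — wide enough
    to cover the visible range of a p-value-function display."""
    theta = np.array([t.estimate for t in trials])
    half_width = 5.0 * max(t.se for t in trials)
    center = float(np.median(theta))
    return np.linspace(center - half_width, center + half_width, n)


def curve_frame(
    trials,
    methods,
    alternative=Alternative.GREATER,
    mu_grid=None,
    n: int = 1001,
) -> pd.DataFrame:
    """Tidy frame of combined p-value curves for external plotting.

    One row per (method, mu) with columns ``method, mu, p_onesided,
    p_twosided``.
    """
    if mu_grid is None:
        mu_grid = default_mu_grid(trials, n)
    mu_grid = np.asarray(mu_grid, dtype=float)
    frames = []
    for method in methods:
        spec = PValueFunctionSpec(tuple(trials), CombinationMethod.parse(method),
                                  Alternative.parse(alternative))
        p = spec.p(mu_grid)
        frames.append(
            pd.DataFrame(
                {
                    "method": spec.method.name,
                    "mu": mu_grid,
                    "p_onesided": p,
                    "p_twosided": centrality(p),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
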