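"""Domain types and standard-error reconstruction for trial summaries.

A trial enters the analysis as an effect estimate on an additive scale (log
rate ratio, log hazard ratio, mean difference, ...) together with its standard
error.  When only a Wald confidence interval or a one-sided p-value is
reported, the standard error is reconstructed under the same normal
approximation that underlies the p-value function machinery.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "Alternative",
    "CombinationMethod",
    "ProbabilityLevel",
    "TrialResult",
    "ValidationError",
    "se_from_ci",
    "se_from_p",
    "trial_from_record",
    "trials_from_records",
]


class ValidationError(ValueError):
    """Raised when an input summary fails validation."""


class Alternative(str, enum.Enum):
    """Direction of the one-sided alternative hypothesis.

    ``GREATER`` means the alternative is that the true effect exceeds the
    null value; ``LESS`` means it is below.  Clinical trials generally have a
    well-defined direction of benefit, so only one-sided alternatives are
    supported.
    """

    GREATER = "greater"
    LESS = "less"

    @classmethod
    def parse(cls, value: "Alternative | str") -> "Alternative":
        if isinstance(value, Alternative):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValidationError(
                f"alternative must be 'greater' or 'less', got {value!r}"
            ) from None


#: Names of the six two-trial combination methods (Wilkinson's general
#: r-of-k rule subsumes the two-trials rule, which is r = k).
METHOD_NAMES = (
    "two_trials_rule",
    "meta_analysis",
    "tippett",
    "fisher",
    "pearson",
    "edgington",
    "wilkinson",
)


@dataclass(frozen=True)
class CombinationMethod:
    """Identifier for a p-value combination method.

    Parameters
    ----------
    name:
        One of ``two_trials_rule`` (squared maximum), ``meta_analysis``
        (inverse-variance weighted Stouffer), ``tippett`` (minimum),
        ``fisher`` (product), ``pearson`` (product of complements),
        ``edgington`` (sum), or ``wilkinson`` (r-th smallest of k).
    wilkinson_r:
        Rank of the order statistic for Wilkinson's method; required for
        ``wilkinson`` and ignored otherwise.
    """

    name: str
    wilkinson_r: int | None = None

    def __post_init__(self) -> None:
        if self.name not in METHOD_NAMES:
            raise ValidationError(
                f"unknown combination method {self.name!r}; "
                f"expected one of {METHOD_NAMES}"
            )
        if self.name == "wilkinson":
            if self.wilkinson_r is None or self.wilkinson_r < 1:
                raise ValidationError(
                    "wilkinson requires a positive integer rank wilkinson_r"
                )
        elif self.wilkinson_r is not None:
            raise ValidationError(
                f"wilkinson_r is only meaningful for the wilkinson method, "
                f"not {self.name!r}"
            )

    @classmethod
    def parse(cls, value: "CombinationMethod | str", wilkinson_r: int | None = None):
        if isinstance(value, CombinationMethod):
            return value
        return cls(str(value).lower(), wilkinson_r)


@dataclass(frozen=True)
class TrialResult:
    """One trial's effect estimate and standard error on an additive scale.

    Attributes
    ----------
    id:
        Label for the trial.
    estimate:
        Effect estimate, already transformed to an additive scale.
    se:
        Positive, finite standard error of the estimate.
    """

    id: str
    estimate: float
    se: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.estimate):
            raise ValidationError(f"trial {self.id!r}: estimate must be finite")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValidationError(
                f"trial {self.id!r}: standard error must be positive and finite, "
                f"got {self.se}"
            )


@dataclass(frozen=True)
class ProbabilityLevel:
    """A probability strictly inside (0, 1), e.g. a confidence level or the
    value ``a`` at which the p-value function is inverted."""

    a: float

    def __post_init__(self) -> None:
        if not (0.0 < self.a < 1.0) or not math.isfinite(self.a):
            raise ValidationError(f"probability level must be in (0, 1), got {self.a}")


def _check_probability(p: float, name: str = "p") -> float:
    p = float(p)
    if not (0.0 < p < 1.0):
        raise ValidationError(f"{name} must lie strictly in (0, 1), got {p}")
    return p


def se_from_ci(lower: float, upper: float, level: float = 0.95) -> float:
    """Standard error from a symmetric Wald confidence interval.

    Assumes ``(lower, upper) = estimate ± z * se`` with
    ``z = Phi^{-1}((1 + level) / 2)``, i.e. a normal-theory two-sided
    interval at the stated level.

    Examples
    --------
    >>> round(se_from_ci(-0.85, -0.13, 0.95), 5)
    0.18368
    """
    lower, upper = float(lower), float(upper)
    if not (math.isfinite(lower) and math.isfinite(upper)):
        raise ValidationError("CI bounds must be finite")
    if not lower < upper:
        raise ValidationError(f"CI bounds inverted: ({lower}, {upper})")
    level = _check_probability(level, "level")
    z = stats.norm.ppf((1.0 + level) / 2.0)
    return (upper - lower) / (2.0 * z)


def se_from_p(
    estimate: float,
    p: float,
    null: float = 0.0,
    alternative: Alternative | str = Alternative.GREATER,
) -> float:
    """Standard error implied by a one-sided p-value at a null value.

    Inverts the normal one-sided p-value: for alternative ``greater``,
    ``p = 1 - Phi((estimate - null) / se)``, so ``se = (estimate - null) /
    Phi^{-1}(1 - p)``; mirrored for ``less``.  ``p = 1/2`` is rejected
    because the z-value is then zero and the standard error unidentified;
    p-values on the wrong side of 1/2 for the observed direction are
    rejected as inconsistent.
    """
    alternative = Alternative.parse(alternative)
    p = _check_probability(p)
    estimate, null = float(estimate), float(null)
    if not (math.isfinite(estimate) and math.isfinite(null)):
        raise ValidationError("estimate and null must be finite")
    # greater: p = 1 - Phi((est - null)/se);  less: p = Phi((est - null)/se)
    z = stats.norm.ppf(1.0 - p if alternative is Alternative.GREATER else p)
    if z == 0.0:
        raise ValidationError("p = 0.5 does not identify a standard error")
    se = (estimate - null) / z
    if not (math.isfinite(se) and se > 0):
        raise ValidationError(
            f"p-value {p} is inconsistent with estimate {estimate}, null {null} "
            f"and alternative {alternative.value!r} (implied se = {se})"
        )
    return se


# -- reading trial summaries from tabular records ---------------------------

#: relative disagreement between uncertainty summaries that triggers a warning
_DISAGREEMENT_TOL = 0.01


def trial_from_record(
    record: dict,
    alternative: Alternative | str = Alternative.GREATER,
    null: float = 0.0,
) -> TrialResult:
    """Build a :class:`TrialResult` from a mapping of column values.

    Recognised keys: ``id``, ``estimate`` and any of ``se`` |
    ``ci_lower``/``ci_upper``/``ci_level`` | ``p_onesided``.  When several
    uncertainty summaries are present the precedence is se > CI > p (the
    standard error is the primitive; CI and p are rounded derivatives), and
    a warning is emitted if they disagree by more than 1% relative.
    """

    def _has(key: str) -> bool:
        v = record.get(key)
        if v is None:
            return False
        try:
            return not math.isnan(float(v))
        except (TypeError, ValueError):
            return False

    if not _has("estimate"):
        raise ValidationError(f"record {record!r} lacks an estimate")
    estimate = float(record["estimate"])
    trial_id = str(record.get("id", ""))

    candidates: dict[str, float] = {}
    if _has("se"):
        candidates["se"] = float(record["se"])
    if _has("ci_lower") and _has("ci_upper"):
        level = float(record["ci_level"]) if _has("ci_level") else 0.95
        candidates["ci"] = se_from_ci(
            float(record["ci_lower"]), float(record["ci_upper"]), level
        )
        mid = (float(record["ci_lower"]) + float(record["ci_upper"])) / 2.0
        if abs(mid - estimate) > _DISAGREEMENT_TOL * max(abs(estimate), 1e-8):
            warnings.warn(
                f"trial {trial_id!r}: CI midpoint {mid:.4g} differs from "
                f"estimate {estimate:.4g}",
                stacklevel=2,
            )
    if _has("p_onesided"):
        candidates["p"] = se_from_p(
            estimate, float(record["p_onesided"]), null, alternative
        )
    if not candidates:
        raise ValidationError(
            f"trial {trial_id!r}: need one of se, (ci_lower, ci_upper), p_onesided"
        )

    for primary in ("se", "ci", "p"):
        if primary in candidates:
            break
    se = candidates[primary]
    for other, value in candidates.items():
        if other != primary and abs(value - se) > _DISAGREEMENT_TOL * se:
            warnings.warn(
                f"trial {trial_id!r}: standard error from {other!r} ({value:.5f}) "
                f"disagrees with the one from {primary!r} ({se:.5f}) by more "
                f"than 1%; using {primary!r}",
                stacklevel=2,
            )
    return TrialResult(id=trial_id, estimate=estimate, se=se)


def trials_from_records(
    records,
    alternative: Alternative | str = Alternative.GREATER,
    null: float = 0.0,
) -> list[TrialResult]:
    """Vector version of :func:`trial_from_record` preserving order."""
    return [trial_from_record(dict(r), alternative, null) for r in records]
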