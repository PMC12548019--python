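"""Published trial summaries used as worked examples.

Two pairs of randomized trials of inhaled ciprofloxacin in non-cystic
fibrosis bronchiectasis: the RESPIRE 1/2 trials (exacerbation rate, log rate
ratio, separate 14-day and 28-day on/off regimens) and the ORBIT 3/4 trials
(primary endpoint: time to first exacerbation, log hazard ratio; secondary
endpoint: exacerbation frequency, log rate ratio).  All values are the
published summary numbers: point estimate, two-sided 95% CI, and one-sided
p-value (alternative "less", since a negative log ratio favours treatment).

Standard errors are reconstructed from the 95% CI (Wald inversion); the
printed one-sided p-values are kept alongside so that combined p-values can
be reproduced exactly from the published per-trial p-values rather than from
the rounded CI-implied ones.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import Alternative, TrialResult, se_from_ci

__all__ = ["Fixture", "FIXTURES", "get_fixture"]


@dataclass(frozen=True)
class Fixture:
    """A named set of published trial summaries.

    ``printed_pvalues`` are the published one-sided per-trial p-values (same
    order as ``trials``); ``provenance`` maps each number back to its
    published source row.
    """

    name: str
    trials: tuple[TrialResult, ...]
    printed_pvalues: tuple[float, ...]
    alternative: Alternative
    effect_scale: str
    provenance: tuple[str, ...]


def _trial(trial_id: str, estimate: float, lower: float, upper: float) -> TrialResult:
    return TrialResult(trial_id, estimate, se_from_ci(lower, upper, 0.95))


FIXTURES: dict[str, Fixture] = {
    "respire_14d": Fixture(
        name="respire_14d",
        trials=(
            _trial("RESPIRE 1", -0.49, -0.85, -0.13),
            _trial("RESPIRE 2", -0.18, -0.53, 0.16),
        ),
        printed_pvalues=(0.00351, 0.14400),
        alternative=Alternative.LESS,
        effect_scale="log rate ratio",
        provenance=(
            "RESPIRE 1, 14-day regimen: log rate ratio -0.49, 95% CI -0.85 to "
            "-0.13, one-sided p 0.00351",
            "RESPIRE 2, 14-day regimen: log rate ratio -0.18, 95% CI -0.53 to "
            "0.16, one-sided p 0.14400",
        ),
    ),
    "respire_28d": Fixture(
        name="respire_28d",
        trials=(
            _trial("RESPIRE 1", -0.02, -0.39, 0.35),
            _trial("RESPIRE 2", -0.60, -0.96, -0.23),
        ),
        printed_pvalues=(0.45699, 0.00064),
        alternative=Alternative.LESS,
        effect_scale="log rate ratio",
        provenance=(
            "RESPIRE 1, 28-day regimen: log rate ratio -0.02, 95% CI -0.39 to "
            "0.35, one-sided p 0.45699",
            "RESPIRE 2, 28-day regimen: log rate ratio -0.60, 95% CI -0.96 to "
            "-0.23, one-sided p 0.00064",
        ),
    ),
    "respire_all4": Fixture(
        name="respire_all4",
        trials=(
            _trial("RESPIRE 1 (14d)", -0.49, -0.85, -0.13),
            _trial("RESPIRE 2 (14d)", -0.18, -0.53, 0.16),
            _trial("RESPIRE 1 (28d)", -0.02, -0.39, 0.35),
            _trial("RESPIRE 2 (28d)", -0.60, -0.96, -0.23),
        ),
        printed_pvalues=(0.00351, 0.14400, 0.45699, 0.00064),
        alternative=Alternative.LESS,
        effect_scale="log rate ratio",
        provenance=(
            "all four RESPIRE estimates (both trials x both regimens), "
            "same source rows as respire_14d and respire_28d",
        ),
    ),
    "orbit_primary": Fixture(
        name="orbit_primary",
        trials=(
            _trial("ORBIT 3", -0.01, -0.34, 0.32),
            _trial("ORBIT 4", -0.33, -0.63, -0.03),
        ),
        printed_pvalues=(0.47636, 0.01657),
        alternative=Alternative.LESS,
        effect_scale="log hazard ratio",
        provenance=(
            "ORBIT 3, time to first exacerbation: log hazard ratio -0.01, 95% "
            "CI -0.34 to 0.32, one-sided p 0.47636",
            "ORBIT 4, time to first exacerbation: log hazard ratio -0.33, 95% "
            "CI -0.63 to -0.03, one-sided p 0.01657",
        ),
    ),
    "orbit_secondary": Fixture(
        name="orbit_secondary",
        trials=(
            _trial("ORBIT 3", -0.16, -0.43, 0.11),
            _trial("ORBIT 4", -0.46, -0.73, -0.19),
        ),
        printed_pvalues=(0.12083, 0.00036),
        alternative=Alternative.LESS,
        effect_scale="log rate ratio",
        provenance=(
            "ORBIT 3, exacerbation frequency: log rate ratio -0.16, 95% CI "
            "-0.43 to 0.11, one-sided p 0.12083",
            "ORBIT 4, exacerbation frequency: log rate ratio -0.46, 95% CI "
            "-0.73 to -0.19, one-sided p 0.00036",
        ),
    ),
}


def get_fixture(name: str) -> Fixture:
    try:
        return FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
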