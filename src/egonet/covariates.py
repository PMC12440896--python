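"""Outcome and covariate recoding rules, equivalent income, diffusion stages.

All recodes are total over their stated category domains and raise on
anything else, so coding errors surface at ingest rather than as silent
NaNs in the design matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structural_holes import tertile_categorize

EXERCISE_LEVELS = ("daily", "5-6/wk", "3-4/wk", "1-2/wk", "few/month", "hardly ever")
ALCOHOL_LEVELS = (
    "daily",
    "5-6/wk",
    "3-4/wk",
    "1-2/wk",
    "few/month",
    "almost never",
    "unable to drink",
)
SMOKING_LEVELS = ("current", "former", "never")
EXERCISE_VARIANTS = ("main", "sens_high", "sens_low")

# Rogers' adopter categories and their shares of the social system (percent)
ADOPTER_SHARES = {
    "innovators": 2.5,
    "early adopters": 13.5,
    "early majority": 34.0,
    "late majority": 34.0,
    "laggards": 16.0,
}

# OECD-modified equivalence scale: first adult / each further adult / each child
OECD_WEIGHTS = (1.0, 0.5, 0.3)

__all__ = [
    "EXERCISE_LEVELS",
    "ALCOHOL_LEVELS",
    "SMOKING_LEVELS",
    "EXERCISE_VARIANTS",
    "ADOPTER_SHARES",
    "OECD_WEIGHTS",
    "EquivalentIncome",
    "equivalent_income",
    "income_categories",
    "recode_exercise",
    "recode_smoking",
    "recode_alcohol",
    "classify_diffusion_stage",
    "cumulative_adopter_share",
]


@dataclass(frozen=True)
class EquivalentIncome:
    value: float | None
    category: str = "unset"  # filled by income_categories

    @property
    def missing(self) -> bool:
        return self.value is None


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x))


def equivalent_income(
    household_income,
    household_adults,
    household_children,
    individual_income,
    weights: tuple[float, float, float] = OECD_WEIGHTS,
) -> EquivalentIncome:
    """Household income adjusted by the OECD-modified equivalence scale.

    Divides household income by ``w0 + w1*(adults-1) + w2*children``
    (1 + 0.5 per additional adult + 0.3 per child by default).  Falls back
    to individual income when household income is missing; missing when
    both are absent.
    """
    if not _is_missing(household_income):
        if household_income < 0:
            raise ValueError("household income must be non-negative")
        if _is_missing(household_adults) or household_adults < 1:
            raise ValueError("household size requires at least one adult")
        children = 0 if _is_missing(household_children) else household_children
        if children < 0:
            raise ValueError("household children count must be non-negative")
        w0, w_adult, w_child = weights
        scale = w0 + w_adult * (household_adults - 1) + w_child * children
        return EquivalentIncome(value=float(household_income) / scale)
    if not _is_missing(individual_income):
        if individual_income < 0:
            raise ValueError("individual income must be non-negative")
        return EquivalentIncome(value=float(individual_income))
    return EquivalentIncome(value=None)


def income_categories(values) -> np.ndarray:
    """Tertile categories {low, middle, high} on observed incomes, plus missing.

    Cut points use the pooled tertile rule on observed values only; egos
    without an income value get the dedicated "missing" category.
    """
    vals = [None if _is_missing(v) else float(v) for v in values]
    observed = np.array([v for v in vals if v is not None])
    out = np.array(["missing"] * len(vals), dtype=object)
    if observed.size:
        cat = tertile_categorize(observed)
        it = iter(cat.labels)
        for i, v in enumerate(vals):
            if v is not None:
                out[i] = next(it)
    return out


def recode_exercise(frequency: str, variant: str = "main") -> int:
    """Binary exercise habit under the main or sensitivity thresholds.

    main: at least 1-2 days/week counts as exercising; sens_high raises
    the bar to 3-4 days/week; sens_low lowers it to a few times a month.
    """
    if frequency not in EXERCISE_LEVELS:
        raise ValueError(f"unknown exercise frequency {frequency!r}")
    if variant not in EXERCISE_VARIANTS:
        raise ValueError(f"unknown recode variant {variant!r}")
    rank = EXERCISE_LEVELS.index(frequency)
    cutoff = {"main": "1-2/wk", "sens_high": "3-4/wk", "sens_low": "few/month"}[variant]
    return int(rank <= EXERCISE_LEVELS.index(cutoff))


def recode_smoking(status: str) -> int:
    """Non-smoking indicator: current smokers 0, former and never 1."""
    if status not in SMOKING_LEVELS:
        raise ValueError(f"unknown smoking status {status!r}")
    return int(status != "current")


def recode_alcohol(frequency: str) -> int:
    """Regular drinking indicator: 3-4 days/week or more often is 1."""
    if frequency not in ALCOHOL_LEVELS:
        raise ValueError(f"unknown alcohol frequency {frequency!r}")
    return int(ALCOHOL_LEVELS.index(frequency) <= ALCOHOL_LEVELS.index("3-4/wk"))


def classify_diffusion_stage(prevalence: float) -> str:
    """Early (<=16%), intermediate (<=50%) or later (>50%) diffusion stage.

    Boundaries follow the cumulative adopter shares: innovators plus early
    adopters cover 16% of the system, adding the early majority reaches
    50%; both boundaries are inclusive on the lower stage.
    """
    if not 0 <= prevalence <= 1:
        raise ValueError("prevalence must lie in [0, 1]")
    if prevalence <= 0.16:
        return "early"
    if prevalence <= 0.50:
        return "intermediate"
    return "later"


def cumulative_adopter_share(categories) -> float:
    """Summed percentage share of a subset of Rogers' adopter categories."""
    total = 0.0
    for cat in categories:
        if cat not in ADOPTER_SHARES:
            raise ValueError(f"unknown adopter category {cat!r}")
        total += ADOPTER_SHARES[cat]
    return total
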