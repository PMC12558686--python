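"""Dichotomization rules for exposure, mediator, outcome, and eligibility.

Raw panel columns (ordinal chewing-ability group, TILS loneliness score,
CES-D depressive-symptom score) are mapped to the binary analysis
variables.  The primary rules: chewing disability = unable to manage the
toughest food group; loneliness = TILS >= 1; clinically significant
depressive symptoms (CSDS) = CES-D >= 7.  Sensitivity variants relax the
exposure rule (groups 1-2 both count as no disability) or tighten the
mediator threshold (TILS >= 4, "mostly lonely").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .errors import CodingError, EligibilityError

EXPOSURE_RULES = ("strict", "lenient")


@dataclass
class CodingRules:
    """Coding configuration for one analysis variant."""

    exposure_rule: str = "strict"  # "strict": group 1 only = no disability
    mediator_threshold: int = 1  # TILS >= threshold = lonely (4 = "mostly lonely")
    outcome_threshold: int = 7  # CES-D >= threshold = CSDS
    continuous_mode: bool = False  # bypass mediator/outcome dichotomization

    def validate(self) -> "CodingRules":
        if self.exposure_rule not in EXPOSURE_RULES:
            raise CodingError(f"exposure_rule must be one of {EXPOSURE_RULES}")
        if not (0 <= self.mediator_threshold <= 12):
            raise CodingError("mediator_threshold must lie in [0, 12]")
        if not (0 <= self.outcome_threshold <= 22):
            raise CodingError("outcome_threshold must lie in [0, 22]")
        return self


def _as_array(x):
    return np.asarray(x, dtype=float)


def code_exposure(chew_group, rule: str = "strict"):
    """Binary chewing disability from the ordinal food-toughness group.

    Group 1 is the toughest food group.  Under the strict rule only group 1
    counts as no disability; under the lenient rule groups 1-2 do.  Missing
    values propagate.
    """
    if rule not in EXPOSURE_RULES:
        raise CodingError(f"unknown exposure rule: {rule!r}")
    arr = _as_array(chew_group)
    valid = np.isnan(arr) | np.isin(arr, [1, 2, 3, 4, 5, 6])
    if not valid.all():
        bad = np.unique(arr[~valid])
        raise CodingError(f"chew_group outside 1-6: {bad.tolist()}")
    cut = 1 if rule == "strict" else 2
    out = np.where(np.isnan(arr), np.nan, (arr > cut).astype(float))
    return out if out.ndim else float(out)


def code_mediator(tils, threshold: int = 1):
    """Binary loneliness: 1 iff TILS score >= threshold."""
    arr = _as_array(tils)
    valid = np.isnan(arr) | ((arr >= 0) & (arr <= 12))
    if not valid.all():
        bad = np.unique(arr[~valid])
        raise CodingError(f"tils outside 0-12: {bad.tolist()}")
    out = np.where(np.isnan(arr), np.nan, (arr >= threshold).astype(float))
    return out if out.ndim else float(out)


def code_outcome(cesd, threshold: int = 7):
    """Binary CSDS: 1 iff CES-D score >= threshold."""
    arr = _as_array(cesd)
    valid = np.isnan(arr) | ((arr >= 0) & (arr <= 22))
    if not valid.all():
        bad = np.unique(arr[~valid])
        raise CodingError(f"cesd outside 0-22: {bad.tolist()}")
    out = np.where(np.isnan(arr), np.nan, (arr >= threshold).astype(float))
    return out if out.ndim else float(out)


@dataclass
class EligibilityResult:
    cohort: CohortTable
    n_input: int
    n_retained: int
    exclusions: dict = field(default_factory=dict)


def apply_eligibility(
    cohort: CohortTable,
    rules: CodingRules | None = None,
    exclude_cognitive: bool = False,
) -> EligibilityResult:
    """Apply baseline eligibility filtering before any analysis.

    In the binary (primary) mode, subjects positive for the outcome at
    baseline and subjects missing baseline exposure or baseline outcome
    status are excluded.  In continuous mode the baseline-outcome exclusion
    is waived (subjects with pre-existing symptoms stay in) and only
    missing baseline exposure excludes.  Optionally subjects flagged at the
    baseline cognitive screen are dropped (a sensitivity variant probing
    differential dropout).  Exclusion reasons are counted so attrition is
    auditable.
    """
    rules = (rules or CodingRules()).validate()
    df = cohort.df
    n_input = len(df)
    exclusions: dict[str, int] = {}

    missing_exposure = df["chew_group_1"].isna()
    keep = ~missing_exposure
    exclusions["missing_baseline_exposure"] = int(missing_exposure.sum())

    if not rules.continuous_mode:
        missing_outcome = df["cesd_1"].isna() & keep
        exclusions["missing_baseline_outcome"] = int(missing_outcome.sum())
        keep &= ~missing_outcome
        baseline_csds = pd.Series(
            code_outcome(df["cesd_1"].to_numpy(), rules.outcome_threshold), index=df.index
        )
        positive = (baseline_csds == 1) & keep
        exclusions["baseline_outcome_positive"] = int(positive.sum())
        keep &= ~positive

    if exclude_cognitive:
        flagged = (df["cognitive_flag"] == 1) & keep
        exclusions["baseline_cognitive_flag"] = int(flagged.sum())
        keep &= ~flagged

    retained = df.loc[keep].reset_index(drop=True)
    if len(retained) == 0:
        raise EligibilityError("no subjects remain after eligibility filtering")
    out = CohortTable(retained, dict(cohort.meta))
    return EligibilityResult(
        cohort=out,
        n_input=n_input,
        n_retained=len(retained),
        exclusions=exclusions,
    )


def code_cohort(cohort: CohortTable, rules: CodingRules | None = None) -> CohortTable:
    """Attach coded analysis columns x_1, x_2, m_1, m_2, y to a cohort.

    In continuous mode the mediator columns carry the raw TILS scores and
    ``y`` the raw wave-3 CES-D score.
    """
    rules = (rules or CodingRules()).validate()
    out = cohort.copy()
    df = out.df
    df["x_1"] = code_exposure(df["chew_group_1"].to_numpy(), rules.exposure_rule)
    df["x_2"] = code_exposure(df["chew_group_2"].to_numpy(), rules.exposure_rule)
    if rules.continuous_mode:
        df["m_1"] = df["tils_1"].to_numpy(dtype=float)
        df["m_2"] = df["tils_2"].to_numpy(dtype=float)
        df["y"] = df["cesd_3"].to_numpy(dtype=float)
    else:
        df["m_1"] = code_mediator(df["tils_1"].to_numpy(), rules.mediator_threshold)
        df["m_2"] = code_mediator(df["tils_2"].to_numpy(), rules.mediator_threshold)
        df["y"] = code_outcome(df["cesd_3"].to_numpy(), rules.outcome_threshold)
    out.meta["coding"] = {
        "exposure_rule": rules.exposure_rule,
        "mediator_threshold": rules.mediator_threshold,
        "outcome_threshold": rules.outcome_threshold,
        "continuous_mode": rules.continuous_mode,
    }
    return out
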