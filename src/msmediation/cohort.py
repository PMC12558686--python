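"""Three-wave cohort container and long-format CSV round-trip.

The cohort is held internally in *wide* form: one row per subject, with
time-varying columns suffixed ``_1``, ``_2``, ``_3`` by wave.  The on-disk
interchange format is *long*: one row per subject-wave, missing cells empty,
which is the natural shape for a panel survey export.

Conventions
-----------
* ``observed_t`` is 1 while the subject is still in the study at wave *t*
  (so censoring is the complement); ``observed_1`` is always 1 and censoring
  is monotone: once 0, always 0.
* Exposure (ordinal chewing-ability group, 1 = toughest foods manageable,
  6 = softest only) and the mediator (TILS loneliness score, 0-12) exist at
  waves 1-2 only; the outcome CES-D score (0-22) at waves 1 and 3 (wave 1 is
  used only for baseline eligibility screening).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CohortValidationError

ETHNICITIES = ("Chinese", "Malay", "Indian", "Others")
HOUSING = ("1-2_room_public", "3_room_public", "4-5_room_or_private")

#: time-invariant subject columns (wide and long share these names)
INVARIANT_COLUMNS = [
    "female",
    "ethnicity",
    "education_low",
    "housing",
    "cognitive_flag",
]

#: base names of time-varying columns; wide form appends _1/_2/_3
TIME_VARYING = [
    "age",
    "mobility",
    "cerebrovascular",
    "coronary_heart",
    "diabetes",
    "cancer",
    "social_support",
    "chew_group",
    "tils",
    "cesd",
    "observed",
]

#: waves at which each time-varying column is defined
WAVES_DEFINED = {
    "age": (1, 2, 3),
    "mobility": (1, 2, 3),
    "cerebrovascular": (1, 2, 3),
    "coronary_heart": (1, 2, 3),
    "diabetes": (1, 2, 3),
    "cancer": (1, 2, 3),
    "social_support": (1, 2, 3),
    "chew_group": (1, 2),
    "tils": (1, 2),
    "cesd": (1, 3),
    "observed": (1, 2, 3),
}

SCORE_RANGES = {"tils": (0, 12), "cesd": (0, 22), "social_support": (0, 60)}

LONG_COLUMNS = ["subject_id", "wave"] + INVARIANT_COLUMNS + TIME_VARYING

DATA_DICTIONARY = """\
column,definition
subject_id,integer subject identifier
wave,survey wave (1 / 2 / 3)
female,1 = female; 0 = male
ethnicity,Chinese / Malay / Indian / Others
education_low,1 = primary school or below
housing,1-2_room_public / 3_room_public / 4-5_room_or_private
cognitive_flag,1 = screened positive for cognitive impairment at baseline (exclusion flag)
age,age in years at the wave
mobility,1 = at least one mobility limitation (Nagi-style index)
cerebrovascular,1 = diagnosed cerebrovascular disease
coronary_heart,1 = diagnosed coronary heart disease
diabetes,1 = diagnosed diabetes mellitus
cancer,1 = diagnosed cancer
social_support,social-support network score (0-60; higher = more support)
chew_group,hardest chewable food group (1 = toughest ... 6 = softest); waves 1-2
tils,three-item loneliness scale total (items 0-4 each; 0-12); waves 1-2
cesd,11-item CES-D depressive-symptom score (0-22); waves 1 and 3
observed,1 = still in study at this wave (censoring indicator complement)
"""


def wide_name(base: str, wave: int) -> str:
    return f"{base}_{wave}"


def wide_columns() -> list[str]:
    cols = ["subject_id"] + list(INVARIANT_COLUMNS)
    for base in TIME_VARYING:
        for t in WAVES_DEFINED[base]:
            cols.append(wide_name(base, t))
    return cols


@dataclass
class CohortTable:
    """A three-wave cohort in wide form (one row per subject)."""

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.df)

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy(), dict(self.meta))

    # -- validation --------------------------------------------------------

    def validate(self) -> "CohortTable":
        df = self.df
        missing_cols = [c for c in wide_columns() if c not in df.columns]
        if missing_cols:
            raise CohortValidationError(f"missing columns: {missing_cols}")
        if df["subject_id"].duplicated().any():
            dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise CohortValidationError(f"duplicate subject ids: {dups[:5]}")

        obs1 = df["observed_1"]
        if not (obs1 == 1).all():
            bad = df.loc[obs1 != 1, "subject_id"].tolist()
            raise CohortValidationError(
                f"observed_1 must be 1 for every subject; offenders: {bad[:5]}"
            )
        # monotone censoring: observed_3 = 1 requires observed_2 = 1
        bad = df.loc[(df["observed_3"] == 1) & (df["observed_2"] == 0), "subject_id"]
        if len(bad):
            raise CohortValidationError(
                "non-monotone censoring (observed at wave 3 but not wave 2) for "
                f"subjects {bad.tolist()[:5]}"
            )

        for base, (lo, hi) in SCORE_RANGES.items():
            for t in WAVES_DEFINED[base]:
                col = wide_name(base, t)
                vals = df[col].dropna()
                out = vals[(vals < lo) | (vals > hi)]
                if len(out):
                    sid = df.loc[out.index, "subject_id"].tolist()
                    raise CohortValidationError(
                        f"{col} outside [{lo},{hi}] for subjects {sid[:5]}"
                    )
        for t in (1, 2):
            col = wide_name("chew_group", t)
            vals = df[col].dropna()
            out = vals[~vals.isin([1, 2, 3, 4, 5, 6])]
            if len(out):
                sid = df.loc[out.index, "subject_id"].tolist()
                raise CohortValidationError(
                    f"{col} outside ordinal range 1-6 for subjects {sid[:5]}"
                )
        bad_eth = df.loc[~df["ethnicity"].isin(ETHNICITIES), "subject_id"]
        if len(bad_eth):
            raise CohortValidationError(f"unknown ethnicity for subjects {bad_eth.tolist()[:5]}")
        bad_house = df.loc[~df["housing"].isin(HOUSING), "subject_id"]
        if len(bad_house):
            raise CohortValidationError(f"unknown housing for subjects {bad_house.tolist()[:5]}")
        return self

    # -- long/wide conversion ---------------------------------------------

    def to_long(self) -> pd.DataFrame:
        rows = []
        for t in (1, 2, 3):
            block = self.df[["subject_id"] + INVARIANT_COLUMNS].copy()
            block.insert(1, "wave", t)
            for base in TIME_VARYING:
                if t in WAVES_DEFINED[base]:
                    block[base] = self.df[wide_name(base, t)].to_numpy()
                else:
                    block[base] = np.nan
            rows.append(block)
        long = pd.concat(rows, ignore_index=True)
        return long.sort_values(["subject_id", "wave"], kind="stable").reset_index(drop=True)[
            LONG_COLUMNS
        ]

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "CohortTable":
        unknown = [c for c in long.columns if c not in LONG_COLUMNS]
        if unknown:
            raise CohortValidationError(f"unknown columns in long table: {unknown}")
        missing = [c for c in LONG_COLUMNS if c not in long.columns]
        if missing:
            raise CohortValidationError(f"missing columns in long table: {missing}")
        base_rows = long[long["wave"] == 1][["subject_id"] + INVARIANT_COLUMNS]
        wide = base_rows.set_index("subject_id")
        for t in (1, 2, 3):
            chunk = long[long["wave"] == t].set_index("subject_id")
            for base in TIME_VARYING:
                if t in WAVES_DEFINED[base]:
                    wide[wide_name(base, t)] = chunk[base]
        wide = wide.reset_index()
        return cls(wide[wide_columns()])

    # -- CSV ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False, na_rep="")

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        long = pd.read_csv(path)
        table = cls.from_long(long)
        return table.validate()


def write_data_dictionary(path) -> None:
    with open(path, "w") as fh:
        fh.write(DATA_DICTIONARY)
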