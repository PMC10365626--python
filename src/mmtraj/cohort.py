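"""Canonical data model for the dynamic cohort.

A cohort is a long person-year table (one row per person per calendar
year, describing status accumulated by December 31 of that year) plus a
per-person timeline (entry/exit years, exit reason, first year of each
outcome).  Persons enter the cohort when they turn 65 or at study start
and are followed until death, loss to follow-up, or study end.

Records for a person must cover contiguous calendar years: a missing year
inside a span is a validation error rather than something to impute.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from mmtraj.catalogs import ConditionCatalog, DeficitCatalog

OUTCOMES = ("death", "nursing_home", "home_care")
EXIT_REASONS = ("death", "lost_to_followup", "study_end")

_BASE_COLUMNS = ["person_id", "year", "age", "sex", "deprivation", "nh_flag", "hc_flag"]
_TIMELINE_COLUMNS = [
    "person_id",
    "entry_year",
    "exit_year",
    "exit_reason",
    "death_year",
    "nh_year",
    "hc_year",
]
_EVENT_COL = {"death": "death_year", "nursing_home": "nh_year", "home_care": "hc_year"}

AGE_MIN, AGE_MAX = 65, 109


class CohortValidationError(ValueError):
    """A record or timeline violates a cohort invariant."""


class SchemaError(ValueError):
    """Input table does not match the documented column schema."""


@dataclass
class Cohort:
    """Long person-year records plus per-person timelines."""

    records: pd.DataFrame
    timelines: pd.DataFrame
    conditions: ConditionCatalog
    deficits: DeficitCatalog

    @property
    def condition_columns(self) -> list[str]:
        return self.conditions.columns()

    @property
    def deficit_columns(self) -> list[str]:
        return self.deficits.columns()

    @property
    def n_persons(self) -> int:
        return self.records["person_id"].nunique()

    def validate(self) -> None:
        validate_cohort(self)


def _require_columns(df: pd.DataFrame, needed: list[str], what: str) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing columns: {missing}")


def validate_cohort(cohort: Cohort) -> None:
    """Check every record and timeline invariant; raise a row-identified error."""
    rec, tl = cohort.records, cohort.timelines
    flag_cols = ["nh_flag", "hc_flag"] + cohort.condition_columns + cohort.deficit_columns
    _require_columns(rec, _BASE_COLUMNS + cohort.condition_columns + cohort.deficit_columns,
                     "cohort table")
    _require_columns(tl, _TIMELINE_COLUMNS, "events table")
    if rec.empty:
        return

    bad_age = rec[(rec["age"] < AGE_MIN) | (rec["age"] > AGE_MAX)]
    if not bad_age.empty:
        r = bad_age.iloc[0]
        raise CohortValidationError(
            f"age {r['age']} out of [{AGE_MIN}, {AGE_MAX}] for person "
            f"{r['person_id']!r} in year {r['year']}"
        )
    dup = rec.duplicated(subset=["person_id", "year"])
    if dup.any():
        r = rec[dup].iloc[0]
        raise CohortValidationError(
            f"duplicate record for person {r['person_id']!r}, year {r['year']}"
        )
    bad_sex = ~rec["sex"].isin(["female", "male"])
    if bad_sex.any():
        r = rec[bad_sex].iloc[0]
        raise CohortValidationError(f"invalid sex {r['sex']!r} for person {r['person_id']!r}")
    dep = rec["deprivation"]
    bad_dep = dep.notna() & ~dep.isin([1, 2, 3, 4, 5])
    if bad_dep.any():
        r = rec[bad_dep].iloc[0]
        raise CohortValidationError(
            f"deprivation {r['deprivation']!r} not in 1..5/missing for person {r['person_id']!r}"
        )
    vals = rec[flag_cols].to_numpy()
    if not np.isin(vals, (0, 1)).all():
        i, j = np.argwhere(~np.isin(vals, (0, 1)))[0]
        raise CohortValidationError(
            f"non-binary value in column {flag_cols[j]!r} for person "
            f"{rec.iloc[i]['person_id']!r}, year {rec.iloc[i]['year']}"
        )

    g = rec.sort_values(["person_id", "year"]).groupby("person_id", sort=False)
    span = g["year"].agg(["min", "max", "size"])
    broken = span[(span["max"] - span["min"] + 1) != span["size"]]
    if not broken.empty:
        raise CohortValidationError(
            f"non-contiguous years for person {broken.index[0]!r}"
        )
    # age attained in the calendar year must track the year
    age_year = (rec["age"] - rec["year"]).groupby(rec["person_id"]).nunique()
    if (age_year > 1).any():
        raise CohortValidationError(
            f"age does not increase with calendar year for person "
            f"{age_year[age_year > 1].index[0]!r}"
        )

    tl = tl.set_index("person_id")
    if tl.index.has_duplicates:
        raise CohortValidationError("duplicate person_id in events table")
    missing_tl = set(rec["person_id"]) - set(tl.index)
    if missing_tl:
        raise CohortValidationError(f"persons without timeline: {sorted(missing_tl)[:5]}")
    bad = tl[tl["entry_year"] > tl["exit_year"]]
    if not bad.empty:
        raise CohortValidationError(f"entry_year > exit_year for person {bad.index[0]!r}")
    bad = tl[~tl["exit_reason"].isin(EXIT_REASONS)]
    if not bad.empty:
        raise CohortValidationError(
            f"invalid exit_reason {bad.iloc[0]['exit_reason']!r} for person {bad.index[0]!r}"
        )
    for col in ("death_year", "nh_year", "hc_year"):
        ev = tl[col]
        out = ev.notna() & ((ev < tl["entry_year"]) | (ev > tl["exit_year"]))
        if out.any():
            raise CohortValidationError(
                f"{col} outside follow-up for person {tl.index[out][0]!r}"
            )
    death_mismatch = tl["death_year"].notna() != (tl["exit_reason"] == "death")
    if death_mismatch.any():
        raise CohortValidationError(
            f"death_year and exit_reason disagree for person "
            f"{tl.index[death_mismatch][0]!r}"
        )
    # records must cover exactly the timeline span
    joined = span.join(tl[["entry_year", "exit_year"]], how="left")
    off = joined[(joined["min"] != joined["entry_year"]) | (joined["max"] != joined["exit_year"])]
    if not off.empty:
        raise CohortValidationError(
            f"records do not cover timeline span for person {off.index[0]!r}"
        )


def derive_timelines(records: pd.DataFrame) -> pd.DataFrame:
    """Build timelines from records alone (no events known: exit = study_end).

    Nursing-home / home-care first years are read off the annual flags.
    """
    if records.empty:
        return pd.DataFrame(columns=_TIMELINE_COLUMNS)
    g = records.sort_values(["person_id", "year"]).groupby("person_id", sort=True)
    tl = g["year"].agg(entry_year="min", exit_year="max").reset_index()
    first = {
        "nh_year": records.loc[records["nh_flag"] == 1].groupby("person_id")["year"].min(),
        "hc_year": records.loc[records["hc_flag"] == 1].groupby("person_id")["year"].min(),
    }
    tl["exit_reason"] = "study_end"
    tl["death_year"] = pd.array([pd.NA] * len(tl), dtype="Int64")
    for col, s in first.items():
        tl[col] = tl["person_id"].map(s).astype("Int64")
    return tl[_TIMELINE_COLUMNS]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix in (".parquet", ".pq"):
        return pd.read_parquet(path)
    try:
        return pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def load_cohort(
    path: str | Path,
    conditions: ConditionCatalog,
    deficits: DeficitCatalog,
    events_path: str | Path | None = None,
) -> Cohort:
    """Read a long person-year table (CSV or Parquet) and its events table.

    Without an events table, timelines are derived from the min/max year
    per person (exit reason ``study_end``) and the annual outcome flags.
    """
    rec = _read_table(path)
    if rec.empty:
        rec = pd.DataFrame(
            columns=_BASE_COLUMNS + conditions.columns() + deficits.columns()
        )
    _require_columns(rec, _BASE_COLUMNS + conditions.columns() + deficits.columns(),
                     "cohort table")
    if events_path is not None:
        tl = _read_table(events_path)
        if tl.empty:
            tl = pd.DataFrame(columns=_TIMELINE_COLUMNS)
        _require_columns(tl, _TIMELINE_COLUMNS, "events table")
        for col in ("death_year", "nh_year", "hc_year"):
            tl[col] = pd.array(tl[col], dtype="Int64")
    else:
        tl = derive_timelines(rec)
    cohort = Cohort(records=rec, timelines=tl, conditions=conditions, deficits=deficits)
    cohort.validate()
    return cohort


def write_cohort(
    cohort: Cohort, path: str | Path, events_path: str | Path | None = None
) -> None:
    """Write records (CSV or Parquet by extension) and, optionally, events CSV."""
    path = Path(path)
    if path.suffix in (".parquet", ".pq"):
        cohort.records.to_parquet(path, index=False)
    else:
        cohort.records.to_csv(path, index=False)
    if events_path is not None:
        cohort.timelines.to_csv(events_path, index=False)


def apply_eligibility(
    cohort: Cohort,
    study_start: int,
    study_end: int,
    max_baseline_age: int = 99,
) -> Cohort:
    """Apply the dynamic-cohort eligibility rules.

    Persons older than ``max_baseline_age`` at ``study_start`` are excluded
    entirely; records outside the study window or before age 65 are dropped;
    persons left with no record are excluded.  Timelines are clipped to the
    surviving span and exit reasons adjusted (an exit at ``study_end`` is
    administrative censoring even if the person was originally lost later).
    """
    if study_start > study_end:
        raise ValueError("study_start must not exceed study_end")
    rec = cohort.records
    if rec.empty:
        return Cohort(rec.copy(), cohort.timelines.copy(), cohort.conditions, cohort.deficits)

    age_at_start = rec["age"] - (rec["year"] - study_start)
    too_old = rec.loc[age_at_start > max_baseline_age, "person_id"].unique()
    keep = (
        ~rec["person_id"].isin(too_old)
        & rec["year"].between(study_start, study_end)
        & (rec["age"] >= AGE_MIN)
    )
    rec = rec.loc[keep].copy()
    kept_ids = rec["person_id"].unique()

    tl = cohort.timelines[cohort.timelines["person_id"].isin(kept_ids)].copy()
    span = rec.groupby("person_id")["year"].agg(["min", "max"])
    tl["entry_year"] = tl["person_id"].map(span["min"])
    tl["exit_year"] = tl["person_id"].map(span["max"])
    for col in ("death_year", "nh_year", "hc_year"):
        tl[col] = tl[col].where(
            tl[col].notna()
            & (tl[col] >= tl["entry_year"])
            & (tl[col] <= tl["exit_year"]),
            pd.NA,
        ).astype("Int64")
    died = tl["death_year"].notna()
    exited_early = tl["exit_year"] < study_end
    tl["exit_reason"] = np.where(
        died, "death", np.where(exited_early, "lost_to_followup", "study_end")
    )
    # a person originally lost before study_end keeps that reason
    orig_lost = cohort.timelines.set_index("person_id")["exit_reason"]
    still_lost = (~died) & (tl["person_id"].map(orig_lost) == "lost_to_followup")
    tl.loc[still_lost & exited_early, "exit_reason"] = "lost_to_followup"

    out = Cohort(rec.reset_index(drop=True), tl.reset_index(drop=True),
                 cohort.conditions, cohort.deficits)
    out.validate()
    return out
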