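"""Pattern characterization: OE ratios, exclusivity, labeling, descriptives.

The observed/expected (OE) ratio of a condition in a pattern is the
condition's prevalence among the pattern's person-years divided by its
prevalence among all person-years; exclusivity is the percentage of all
individuals with the condition who belong to the pattern.  A condition is
considered associated with a pattern when OE >= 2 or exclusivity >= 25%.

Units are deliberately asymmetric: OE uses person-years (prevalence is a
record-level notion) while exclusivity uses individuals.  A person whose
years fall in several patterns counts toward each of them for exclusivity,
so per-condition exclusivities sum to >= 100%; the sum equals 100% exactly
when no person with the condition spans two patterns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mmtraj.cohort import Cohort
from mmtraj.status import frailty_category, multimorbidity_band


def _merge(assignments: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    df = records.merge(assignments[["person_id", "year", "pattern"]],
                       on=["person_id", "year"], how="left")
    if df["pattern"].isna().any():
        raise ValueError("every person-year record must be assigned to a pattern")
    return df


def oe_ratio(assignments: pd.DataFrame, cohort: Cohort, condition: str) -> pd.Series:
    """Per-pattern OE ratio for one condition (NaN if absent everywhere)."""
    df = _merge(assignments, cohort.records)
    col = f"cond_{condition}"
    overall = df[col].mean()
    if overall == 0:
        return pd.Series(np.nan, index=sorted(df["pattern"].unique()), name=condition)
    return df.groupby("pattern")[col].mean() / overall


def exclusivity(assignments: pd.DataFrame, cohort: Cohort, condition: str) -> pd.Series:
    """Per-pattern exclusivity (%) for one condition.

    An individual counts in a pattern if any of their person-years is
    assigned to it while the condition is active.
    """
    df = _merge(assignments, cohort.records)
    col = f"cond_{condition}"
    with_cond = df[df[col] == 1]
    n_persons = with_cond["person_id"].nunique()
    if n_persons == 0:
        return pd.Series(np.nan, index=sorted(df["pattern"].unique()), name=condition)
    per_pattern = with_cond.groupby("pattern")["person_id"].nunique()
    out = per_pattern.reindex(sorted(df["pattern"].unique()), fill_value=0)
    return 100.0 * out / n_persons


def profile_patterns(
    assignments: pd.DataFrame,
    cohort: Cohort,
    oe_threshold: float = 2.0,
    excl_threshold: float = 25.0,
) -> pd.DataFrame:
    """Full profile table: one row per (pattern, condition).

    Columns: prevalence in pattern and overall (person-year %), OE ratio,
    exclusivity (%), and the associated flag (OE >= 2 OR exclusivity >= 25).
    Rows are sorted within each pattern by OE descending.
    """
    df = _merge(assignments, cohort.records)
    cond_cols = cohort.condition_columns
    patterns = np.sort(df["pattern"].unique())

    overall = df[cond_cols].mean()
    by_pat = df.groupby("pattern")[cond_cols].mean()
    counts = df.groupby("pattern").size()

    rows = []
    # individual-level attribution per (pattern, condition)
    person_pat_cond: dict[str, pd.Series] = {}
    for col in cond_cols:
        with_c = df[df[col] == 1]
        person_pat_cond[col] = (
            with_c.groupby("pattern")["person_id"].nunique(),
            with_c["person_id"].nunique(),
        )
    for pat in patterns:
        for code, col in zip(cohort.conditions.codes, cond_cols):
            prev_overall = overall[col]
            prev_pat = by_pat.loc[pat, col]
            oe = np.nan if prev_overall == 0 else prev_pat / prev_overall
            per_pattern, n_with = person_pat_cond[col]
            excl = (np.nan if n_with == 0
                    else 100.0 * per_pattern.get(pat, 0) / n_with)
            associated = (not np.isnan(oe) and oe >= oe_threshold) or (
                not np.isnan(excl) and excl >= excl_threshold)
            rows.append({
                "pattern": pat, "condition": code,
                "prev_pattern": 100.0 * prev_pat,
                "prev_overall": 100.0 * prev_overall,
                "oe": oe, "exclusivity": excl,
                "associated": associated,
                "pattern_person_years": int(counts[pat]),
            })
    out = pd.DataFrame(rows)
    return out.sort_values(["pattern", "oe"], ascending=[True, False]).reset_index(drop=True)


def label_conditions(
    profile: pd.DataFrame,
    oe_threshold: float = 2.0,
    excl_threshold: float = 25.0,
) -> dict[int, list[str]]:
    """Associated-condition lists per pattern, sorted by OE descending."""
    prof = profile.copy()
    prof["associated"] = (
        (prof["oe"] >= oe_threshold) | (prof["exclusivity"] >= excl_threshold)
    )
    out: dict[int, list[str]] = {}
    for pat, grp in prof.groupby("pattern"):
        sel = grp[grp["associated"]].sort_values("oe", ascending=False)
        out[int(pat)] = sel["condition"].tolist()
    return out


def describe_pattern(assignments: pd.DataFrame, cohort: Cohort) -> pd.DataFrame:
    """Per-pattern descriptive block over all person-years assigned to it.

    Reports age median/IQR, sex %, deprivation distribution (missing
    excluded from the denominator), multimorbidity bands, frailty
    categories, median condition/deficit counts, and outcome-flag
    percentages.  Empty patterns are omitted.
    """
    df = _merge(assignments, cohort.records)
    cond_cols, def_cols = cohort.condition_columns, cohort.deficit_columns
    blocks = []
    for pat, grp in df.groupby("pattern"):
        ncond = grp[cond_cols].sum(axis=1)
        ndef = grp[def_cols].sum(axis=1)
        band = multimorbidity_band(ncond.to_numpy())
        fcat = frailty_category(ndef.to_numpy(), cohort.deficits.size)
        dep = grp["deprivation"].dropna()
        block = {
            "pattern": pat,
            "person_years": len(grp),
            "persons": grp["person_id"].nunique(),
            "age_median": grp["age"].median(),
            "age_q1": grp["age"].quantile(0.25),
            "age_q3": grp["age"].quantile(0.75),
            "pct_female": 100.0 * (grp["sex"] == "female").mean(),
            "conditions_median": ncond.median(),
            "deficits_median": ndef.median(),
            "pct_nursing_home": 100.0 * grp["nh_flag"].mean(),
            "pct_home_care": 100.0 * grp["hc_flag"].mean(),
        }
        for q in (1, 2, 3, 4, 5):
            block[f"pct_deprivation_{q}"] = (
                100.0 * (dep == q).mean() if len(dep) else np.nan
            )
        for b in ("0-1", "2-5", "6-10", ">10"):
            block[f"pct_band_{b}"] = 100.0 * (band == b).mean()
        for f in ("fit", "mild", "moderate", "severe"):
            block[f"pct_{f}"] = 100.0 * (fcat == f).mean()
        blocks.append(block)
    return pd.DataFrame(blocks).sort_values("pattern").reset_index(drop=True)
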