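"""Pattern trajectories, trajectory statistics, and transition matrices.

A trajectory is the ordered sequence of a person's annually assigned
patterns over follow-up.  The terminal state is death when follow-up
ended in death, otherwise the last observed pattern (persons lost to
follow-up contribute their last observed pattern; there is no separate
censoring column).  The transition matrix conditions on the pattern in
the first year of inclusion and reports the distribution over last
patterns plus death.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mmtraj.cohort import Cohort

DEATH = "death"


def build_trajectories(
    assignments: pd.DataFrame, timelines: pd.DataFrame
) -> pd.DataFrame:
    """One row per person: first/last pattern, distinct count, switches,
    stability flag, terminal state, and follow-up length.

    Assigned years must exactly cover each person's follow-up span
    (contiguity contract); gaps raise an error.
    """
    a = assignments.sort_values(["person_id", "year"], kind="mergesort")
    tl = timelines.set_index("person_id")
    g = a.groupby("person_id", sort=True)
    span = g["year"].agg(["min", "max", "size"])
    if ((span["max"] - span["min"] + 1) != span["size"]).any():
        bad = span[(span["max"] - span["min"] + 1) != span["size"]].index[0]
        raise ValueError(f"assignment gap for person {bad!r}")
    missing = set(span.index) - set(tl.index)
    if missing:
        raise ValueError(f"persons without timeline: {sorted(missing)[:5]}")
    cover = tl.loc[span.index]
    if ((span["min"] != cover["entry_year"]) | (span["max"] != cover["exit_year"])).any():
        bad = span.index[(span["min"] != cover["entry_year"])
                         | (span["max"] != cover["exit_year"])][0]
        raise ValueError(f"assignments do not cover follow-up for person {bad!r}")

    rows = []
    for pid, grp in g:
        seq = grp["pattern"].to_numpy()
        n_distinct = len(np.unique(seq))
        n_switches = int((seq[1:] != seq[:-1]).sum())
        died = tl.loc[pid, "exit_reason"] == "death"
        rows.append({
            "person_id": pid,
            "first_pattern": seq[0],
            "last_pattern": seq[-1],
            "terminal_state": DEATH if died else seq[-1],
            "n_distinct": n_distinct,
            "n_switches": n_switches,
            "stable": n_distinct == 1,
            "length": len(seq),
        })
    return pd.DataFrame(rows)


def trajectory_stats(
    trajectories: pd.DataFrame, stratify_by_length: bool = False
) -> dict:
    """Mean distinct-pattern count, mean switch count, and % stable.

    With ``stratify_by_length`` a per-follow-up-length table is included.
    """
    if trajectories.empty:
        raise ValueError("trajectory set is empty")
    out = {
        "n": len(trajectories),
        "mean_n_distinct": float(trajectories["n_distinct"].mean()),
        "mean_n_switches": float(trajectories["n_switches"].mean()),
        "pct_stable": 100.0 * float(trajectories["stable"].mean()),
    }
    if stratify_by_length:
        tab = trajectories.groupby("length").agg(
            n=("person_id", "size"),
            mean_n_distinct=("n_distinct", "mean"),
            mean_n_switches=("n_switches", "mean"),
            pct_stable=("stable", lambda s: 100.0 * s.mean()),
        ).reset_index()
        out["by_length"] = tab
    return out


@dataclass
class TransitionMatrix:
    """First-pattern -> (last pattern | death) conditional proportions."""

    matrix: pd.DataFrame           # index first patterns, columns patterns + death
    row_counts: pd.Series
    omitted_rows: list


def transition_matrix(trajectories: pd.DataFrame) -> TransitionMatrix:
    """Row-conditional first-to-last transition proportions including death."""
    patterns = np.sort(
        np.unique(np.concatenate([
            trajectories["first_pattern"].unique(),
            trajectories[trajectories["terminal_state"] != DEATH]
            ["terminal_state"].unique(),
        ]))
    ) if len(trajectories) else np.array([])
    cols = list(patterns) + [DEATH]
    tab = pd.crosstab(trajectories["first_pattern"], trajectories["terminal_state"])
    tab = tab.reindex(index=patterns, columns=cols, fill_value=0)
    row_counts = tab.sum(axis=1)
    omitted = row_counts[row_counts == 0].index.tolist()
    tab = tab.loc[row_counts > 0]
    mat = tab.div(tab.sum(axis=1), axis=0)
    return TransitionMatrix(matrix=mat, row_counts=row_counts[row_counts > 0],
                            omitted_rows=omitted)


def prevalence_by_age(assignments: pd.DataFrame, cohort: Cohort) -> pd.DataFrame:
    """Share of each integer age's person-years in each pattern.

    Pools all calendar years (a person contributes at every age observed);
    shares sum to 1 within each age; ages with no records are absent.
    """
    df = cohort.records[["person_id", "year", "age"]].merge(
        assignments[["person_id", "year", "pattern"]],
        on=["person_id", "year"], how="inner")
    tab = pd.crosstab(df["age"], df["pattern"])
    return tab.div(tab.sum(axis=1), axis=0)
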