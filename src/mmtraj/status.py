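"""Per-person-year multimorbidity and frailty summaries and feature sets.

Frailty follows the cumulative-deficit model: the index is the proportion
of accumulated deficits out of the catalog, categorized with the standard
cutoffs (fit < 0.12, mild 0.12-0.24, moderate 0.24-0.36, severe >= 0.36;
intervals closed on the left).  Multimorbidity is two or more chronic
conditions.

Two clustering feature sets share the prevalence-filtered condition
indicators and differ in one extra quantitative column: the person's age
("multimorbidity & age") or their deficit count ("multimorbidity &
frailty").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mmtraj.cohort import Cohort

FRAILTY_CUTOFFS = (0.12, 0.24, 0.36)
FRAILTY_CATEGORIES = ("fit", "mild", "moderate", "severe")
VARIANTS = ("age", "frailty")
_EXTRA_COLUMN = {"age": "age", "frailty": "n_deficits"}


@dataclass(frozen=True)
class FrailtyStatus:
    n_deficits: int
    index: float
    category: str


@dataclass(frozen=True)
class MultimorbidityStatus:
    n_conditions: int
    multimorbid: bool
    band: str


def frailty_category(n_deficits: np.ndarray, catalog_size: int) -> np.ndarray:
    """Vectorized frailty category from deficit counts (left-closed cutoffs)."""
    index = np.asarray(n_deficits, dtype=float) / catalog_size
    out = np.full(index.shape, "fit", dtype=object)
    out[index >= FRAILTY_CUTOFFS[0]] = "mild"
    out[index >= FRAILTY_CUTOFFS[1]] = "moderate"
    out[index >= FRAILTY_CUTOFFS[2]] = "severe"
    return out


def frailty_status(deficit_vector: np.ndarray, catalog_size: int | None = None) -> FrailtyStatus:
    """Frailty index and category from a binary deficit vector.

    ``index = sum(deficits) / catalog_size``; category by the half-open
    intervals [0, 0.12), [0.12, 0.24), [0.24, 0.36), [0.36, 1].
    """
    vec = np.asarray(deficit_vector)
    size = catalog_size if catalog_size is not None else vec.size
    if vec.size != size:
        raise ValueError(f"deficit vector has length {vec.size}, expected {size}")
    n = int(vec.sum())
    return FrailtyStatus(n, n / size, str(frailty_category(np.array([n]), size)[0]))


def multimorbidity_band(n_conditions: np.ndarray) -> np.ndarray:
    n = np.asarray(n_conditions)
    out = np.full(n.shape, "0-1", dtype=object)
    out[n >= 2] = "2-5"
    out[n >= 6] = "6-10"
    out[n > 10] = ">10"
    return out


def multimorbidity_status(condition_vector: np.ndarray) -> MultimorbidityStatus:
    n = int(np.asarray(condition_vector).sum())
    return MultimorbidityStatus(n, n >= 2, str(multimorbidity_band(np.array([n]))[0]))


class AllConditionsRemovedError(ValueError):
    """The prevalence filter removed every condition; clustering is impossible."""


def prevalence_filter(
    cohort: Cohort, threshold: float = 0.02
) -> tuple[list[str], pd.DataFrame]:
    """Retain conditions whose mean annual prevalence is >= ``threshold``.

    The mean annual prevalence of a condition is the unweighted mean over
    calendar years of its prevalence among that year's person-year records.
    Returns the retained condition codes (catalog order) and an audit table
    ``condition, year, prevalence, mean_prevalence, retained``.
    """
    rec = cohort.records
    if rec.empty:
        raise ValueError("prevalence filter requires at least one year of records")
    cond_cols = cohort.condition_columns
    per_year = rec.groupby("year")[cond_cols].mean()  # year x condition
    mean_prev = per_year.mean(axis=0)
    # a never-observed condition is never retained, even at threshold 0
    retained_mask = (mean_prev >= threshold) & (mean_prev > 0)
    retained = [c for c, col in zip(cohort.conditions.codes, cond_cols) if retained_mask[col]]

    audit = per_year.reset_index().melt(
        id_vars="year", var_name="condition", value_name="prevalence"
    )
    audit["condition"] = audit["condition"].str.removeprefix("cond_")
    audit["mean_prevalence"] = audit["condition"].map(
        {c.removeprefix("cond_"): v for c, v in mean_prev.items()}
    )
    audit["retained"] = audit["condition"].isin(retained)
    audit = audit.sort_values(["condition", "year"]).reset_index(drop=True)

    if not retained:
        raise AllConditionsRemovedError(
            f"no condition reaches mean annual prevalence {threshold}"
        )
    return retained, audit


@dataclass
class FeatureMatrix:
    """Clustering input: binary condition columns plus one quantitative column.

    ``data`` has one row per person-year ordered by (person_id, year);
    ``categorical`` lists the retained condition columns, ``quantitative``
    the single extra column determined by ``variant``.
    """

    data: pd.DataFrame
    categorical: list[str]
    quantitative: list[str]
    variant: str
    person_id: np.ndarray
    year: np.ndarray


def build_feature_matrix(
    cohort: Cohort, retained: list[str], variant: str
) -> FeatureMatrix:
    """Assemble the clustering feature matrix for one feature-set variant."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if not retained:
        raise ValueError("retained condition list must be non-empty")
    rec = cohort.records.sort_values(["person_id", "year"], kind="mergesort")
    cond_cols = [f"cond_{c}" for c in retained]
    missing = [c for c in cond_cols if c not in rec.columns]
    if missing:
        raise ValueError(f"retained conditions absent from records: {missing}")
    data = rec[cond_cols].astype(int).reset_index(drop=True)
    extra = _EXTRA_COLUMN[variant]
    if variant == "age":
        data[extra] = rec["age"].to_numpy(dtype=float)
    else:
        data[extra] = rec[cohort.deficit_columns].sum(axis=1).to_numpy(dtype=float)
    return FeatureMatrix(
        data=data,
        categorical=cond_cols,
        quantitative=[extra],
        variant=variant,
        person_id=rec["person_id"].to_numpy(),
        year=rec["year"].to_numpy(),
    )
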