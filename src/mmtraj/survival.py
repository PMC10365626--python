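"""Time-varying-covariate survival models for pattern-outcome association.

The annually assigned multimorbidity pattern is the sole covariate, coded
as a time-varying categorical in counting-process (start-stop) form: one
row per person-year interval ``[t, t + 1)`` on the time scale of years
since cohort entry.  All-cause mortality uses a Cox proportional-hazards
fit; nursing-home admission and home-care need use cause-specific Cox
fits in which death is a competing risk handled by censoring at the death
time (the multistate convention).

Each fit reports hazard ratios against a reference pattern, AIC from the
partial likelihood, a likelihood-ratio pseudo-R-squared, a concordance
statistic over comparable pairs under the counting-process representation,
and a Schoenfeld-residual check of proportional hazards (correlation of
per-event residuals with event time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxTimeVaryingFitter
from scipy import stats

from mmtraj.cohort import OUTCOMES

_EVENT_COL = {"death": "death_year", "nursing_home": "nh_year", "home_care": "hc_year"}


class NoFitError(ValueError):
    """The table cannot support a fit (no events or a single pattern)."""


def build_counting_process(
    assignments: pd.DataFrame, timelines: pd.DataFrame, outcome: str
) -> pd.DataFrame:
    """Annual start-stop table for one outcome.

    For the non-fatal outcomes, follow-up stops at the earliest of the
    outcome year, death (competing risk, censored), loss to follow-up, and
    study end; for death it stops at death/censoring.  The event flag is 1
    only on the final interval and only when the outcome occurred.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    df = assignments[["person_id", "year", "pattern"]].merge(
        timelines[["person_id", "entry_year", "exit_year", _EVENT_COL[outcome]]],
        on="person_id", how="left")
    if df["entry_year"].isna().any():
        bad = df.loc[df["entry_year"].isna(), "person_id"].iloc[0]
        raise ValueError(f"person {bad!r} has assignments but no timeline")
    ev = df[_EVENT_COL[outcome]].astype("Float64")
    if ((ev.notna()) & (ev < df["entry_year"])).any():
        bad = df.loc[ev.notna() & (ev < df["entry_year"]), "person_id"].iloc[0]
        raise ValueError(f"outcome before cohort entry for person {bad!r}")
    stop_year = df["exit_year"].where(ev.isna(), np.minimum(df["exit_year"], ev))
    keep = df["year"] <= stop_year
    out = df.loc[keep, ["person_id", "year", "pattern"]].copy()
    out["t_start"] = (df.loc[keep, "year"] - df.loc[keep, "entry_year"]).astype(int)
    out["t_stop"] = out["t_start"] + 1
    out["event"] = (ev.loc[keep].notna() & (df.loc[keep, "year"] == ev.loc[keep])).astype(int)
    return out[["person_id", "t_start", "t_stop", "pattern", "event"]].reset_index(drop=True)


@dataclass
class SurvivalFit:
    outcome: str
    variant: str
    reference: object
    hazard_ratios: pd.DataFrame      # pattern, hr, ci_low, ci_high, p
    aic: float
    r2: float
    cindex: float
    schoenfeld_p: dict[str, float]
    log_likelihood: float
    null_log_likelihood: float
    lr_statistic: float
    n_events: int
    n_persons: int
    dropped_patterns: list = field(default_factory=list)


def _design(table: pd.DataFrame, reference) -> tuple[pd.DataFrame, list]:
    patterns = sorted(table["pattern"].unique())
    if reference not in patterns:
        raise ValueError(f"reference pattern {reference!r} not present in table")
    levels = [p for p in patterns if p != reference]
    X = pd.DataFrame({f"pattern_{p}": (table["pattern"] == p).astype(float)
                      for p in levels}, index=table.index)
    return X, levels


def _time_varying_concordance(table: pd.DataFrame, lp: np.ndarray) -> float:
    """Concordance over comparable pairs in the counting-process table.

    At each event time t, the comparable pairs are (event row, at-risk
    non-event row); a pair is concordant when the event row's linear
    predictor is higher, and ties in the predictor count one half.
    """
    t_start = table["t_start"].to_numpy()
    t_stop = table["t_stop"].to_numpy()
    event = table["event"].to_numpy().astype(bool)
    conc = ties = total = 0.0
    for t in np.unique(t_stop[event]):
        at_risk = (t_start < t) & (t <= t_stop)
        ev_here = event & (t_stop == t)
        others = at_risk & ~ev_here
        if not others.any():
            continue
        other_sorted = np.sort(lp[others])
        for v in lp[ev_here]:
            lo = np.searchsorted(other_sorted, v, side="left")
            hi = np.searchsorted(other_sorted, v, side="right")
            conc += lo
            ties += hi - lo
            total += len(other_sorted)
    if total == 0:
        return float("nan")
    return (conc + 0.5 * ties) / total


def _schoenfeld_check(
    table: pd.DataFrame, X: pd.DataFrame, beta: np.ndarray
) -> dict[str, float]:
    """Trend test on Schoenfeld residuals: per-covariate Pearson correlation
    of the residual with event time (Breslow risk-set weighting)."""
    t_start = table["t_start"].to_numpy()
    t_stop = table["t_stop"].to_numpy()
    event = table["event"].to_numpy().astype(bool)
    Xv = X.to_numpy()
    w = np.exp(Xv @ beta)
    resid, times = [], []
    for t in np.unique(t_stop[event]):
        at_risk = (t_start < t) & (t <= t_stop)
        xbar = (w[at_risk, None] * Xv[at_risk]).sum(axis=0) / w[at_risk].sum()
        for xi in Xv[event & (t_stop == t)]:
            resid.append(xi - xbar)
            times.append(t)
    R = np.asarray(resid)
    times = np.asarray(times, dtype=float)
    out = {}
    for j, col in enumerate(X.columns):
        r = R[:, j]
        if len(r) < 3 or np.allclose(r, r[0]) or np.allclose(times, times[0]):
            out[col] = float("nan")
        else:
            out[col] = float(stats.pearsonr(times, r).pvalue)
    return out


def fit_cox_timevarying(
    table: pd.DataFrame,
    reference_pattern,
    outcome: str = "",
    variant: str = "",
) -> SurvivalFit:
    """Cox proportional-hazards fit with the pattern as the sole
    time-varying categorical covariate.

    Patterns with no events and no person-time are dropped with a warning;
    zero events overall or a single pattern raise :class:`NoFitError`.
    """
    table = table.copy()
    n_events = int(table["event"].sum())
    if n_events == 0:
        raise NoFitError("no events in the counting-process table")
    present = table.groupby("pattern").agg(
        time=("t_stop", "size"), events=("event", "sum"))
    dead_levels = present[(present["time"] == 0) & (present["events"] == 0)].index.tolist()
    if dead_levels:
        warnings.warn(f"dropping empty pattern levels: {dead_levels}")
        table = table[~table["pattern"].isin(dead_levels)]
    if table["pattern"].nunique() < 2:
        raise NoFitError("fewer than two patterns present; nothing to contrast")

    X, levels = _design(table, reference_pattern)
    fit_df = pd.concat(
        [table[["person_id", "t_start", "t_stop", "event"]].reset_index(drop=True),
         X.reset_index(drop=True)], axis=1)
    ctv = CoxTimeVaryingFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ctv.fit(fit_df, id_col="person_id", event_col="event",
                start_col="t_start", stop_col="t_stop",
                fit_options={"precision": 1e-9})

    summ = ctv.summary
    hr_rows = [{"pattern": reference_pattern, "hr": 1.0,
                "ci_low": np.nan, "ci_high": np.nan, "p": np.nan}]
    with np.errstate(over="ignore"):  # an unstable level can give an infinite CI
        for p in levels:
            row = summ.loc[f"pattern_{p}"]
            hr_rows.append({"pattern": p, "hr": float(np.exp(row["coef"])),
                            "ci_low": float(np.exp(row["coef lower 95%"])),
                            "ci_high": float(np.exp(row["coef upper 95%"])),
                            "p": float(row["p"])})
    hr = pd.DataFrame(hr_rows)

    ll = float(ctv.log_likelihood_)
    lr = float(ctv.log_likelihood_ratio_test().test_statistic)
    ll0 = ll - lr / 2.0
    n_persons = table["person_id"].nunique()
    r2 = 1.0 - float(np.exp(-lr / n_persons))
    beta = summ["coef"].to_numpy()
    lp = X.to_numpy() @ beta
    cindex = _time_varying_concordance(table, lp)
    sch = _schoenfeld_check(table, X, beta)
    return SurvivalFit(
        outcome=outcome, variant=variant, reference=reference_pattern,
        hazard_ratios=hr, aic=float(ctv.AIC_partial_), r2=r2, cindex=cindex,
        schoenfeld_p=sch, log_likelihood=ll, null_log_likelihood=ll0,
        lr_statistic=lr, n_events=n_events, n_persons=n_persons,
        dropped_patterns=dead_levels)


def fit_cause_specific(
    table_outcome: pd.DataFrame,
    table_death: pd.DataFrame | None = None,
    reference_pattern=None,
    outcome: str = "",
    variant: str = "",
) -> SurvivalFit:
    """Cause-specific hazard fit for a non-fatal outcome.

    ``table_outcome`` must come from :func:`build_counting_process`, which
    already censors follow-up at death (the cause-specific/multistate
    convention); ``table_death`` is accepted for a consistency check that
    the two tables describe the same persons.
    """
    if table_death is not None:
        only = set(table_outcome["person_id"]) - set(table_death["person_id"])
        if only:
            raise ValueError(
                f"outcome table contains persons absent from the death table: "
                f"{sorted(only)[:5]}")
    return fit_cox_timevarying(table_outcome, reference_pattern,
                               outcome=outcome, variant=variant)


METRICS = {"aic": "lower", "r2": "higher", "cindex": "higher"}


def compare_variants(
    fits_age: dict[str, SurvivalFit], fits_frailty: dict[str, SurvivalFit]
) -> pd.DataFrame:
    """Per-outcome, per-metric comparison of the two feature-set variants.

    Marks which variant performs better on each metric (AIC lower-better;
    pseudo-R-squared and concordance higher-better); exact ties are flagged.
    """
    if set(fits_age) != set(fits_frailty):
        raise ValueError(
            f"variant fits cover different outcomes: {sorted(fits_age)} vs "
            f"{sorted(fits_frailty)}")
    rows = []
    for outcome in sorted(fits_age):
        fa, ff = fits_age[outcome], fits_frailty[outcome]
        if fa.n_persons != ff.n_persons:
            raise ValueError(f"mismatched cohorts for outcome {outcome!r}")
        for metric, direction in METRICS.items():
            va, vf = getattr(fa, metric), getattr(ff, metric)
            if va == vf:
                better = "tie"
            elif (va < vf) == (direction == "lower"):
                better = "age"
            else:
                better = "frailty"
            rows.append({"outcome": outcome, "metric": metric,
                         "age": va, "frailty": vf, "better": better})
    return pd.DataFrame(rows)
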