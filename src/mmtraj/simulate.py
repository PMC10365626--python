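"""Synthetic dynamic-cohort generator with planted multimorbidity structure.

Emulates an open cohort of people aged 65+ followed annually over a study
window: staggered entry (present at baseline or turning 65 later),
irreversible (chronic) condition onset whose probability rises with age,
planted latent disease clusters (each person belongs to one pattern whose
signature conditions have elevated onset), a cumulative-deficit frailty
count correlated with conditions and age, and discrete-time hazards for
death, nursing-home admission, and home-care need that depend on the
planted pattern (and optionally on the deficit count).

The generator exists so that every downstream stage — feature building,
mixed-data factorization, fuzzy clustering, profiling, trajectories, and
survival modelling — can be exercised and checked against known ground
truth without access to any real primary-care database.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from mmtraj.catalogs import ConditionCatalog, DeficitCatalog
from mmtraj.cohort import AGE_MAX, Cohort, derive_timelines

OUTCOMES = ("death", "nursing_home", "home_care")


class EmptyCohortError(ValueError):
    """Summary requested for an empty cohort."""


@dataclass
class ScenarioConfig:
    """Parameters of a simulated scenario.

    Onset model: a person in planted pattern ``g`` acquires condition ``c``
    in a year at age ``a`` with probability
    ``expit(logit(loadings[g, c]) + age_slope[c] * (a - 65))``; once active a
    condition stays active.  Default loadings give each pattern a disjoint
    block of ``signature_size`` conditions at ``signature_onset`` per year,
    all other conditions at ``baseline_onset``.

    Deficit model: the annual deficit count is
    ``Binomial(n_deficits, expit(b0 + b1 * n_conditions + b2 * (age - 65)))``;
    which deficits are set is uniform given the count.

    Outcome model: discrete annual hazards
    ``h = baseline_hazard[o] * exp(hazard_log_hr[g, o] + deficit_log_hr[o] * n_deficits)``
    with event probability ``1 - exp(-h)``; same-year ties resolve
    death > nursing home > home care (death censors the non-fatal events).
    """

    n_persons: int = 5000
    study_start: int = 2010
    study_end: int = 2019
    n_patterns_true: int = 5
    n_conditions: int = 60
    n_deficits: int = 36
    signature_size: int = 12
    signature_onset: float = 0.2
    baseline_onset: float = 0.004
    age_slope: float = 0.05
    condition_loadings: np.ndarray | None = None
    deficit_intercept: float = -2.94
    deficit_cond_coef: float = 0.08
    deficit_age_coef: float = 0.03
    baseline_hazard: dict[str, float] = field(
        default_factory=lambda: {"death": 0.02, "nursing_home": 0.008, "home_care": 0.012}
    )
    hazard_log_hr: np.ndarray | None = None
    deficit_log_hr: dict[str, float] = field(
        default_factory=lambda: {o: 0.0 for o in OUTCOMES}
    )
    baseline_fraction: float = 0.6
    entry_age_scale: float = 8.0
    censoring_rate: float = 0.02
    female_fraction: float = 0.56
    deprivation_missing: float = 0.1
    seed: int = 0

    def loadings(self) -> np.ndarray:
        """Per-pattern, per-condition annual onset probability at age 65."""
        if self.condition_loadings is not None:
            arr = np.asarray(self.condition_loadings, dtype=float)
            if arr.shape != (self.n_patterns_true, self.n_conditions):
                raise ValueError(
                    "condition_loadings must be (n_patterns_true, n_conditions)"
                )
            return arr
        arr = np.full((self.n_patterns_true, self.n_conditions), self.baseline_onset)
        for g in range(self.n_patterns_true):
            lo = (g * self.signature_size) % self.n_conditions
            idx = (lo + np.arange(self.signature_size)) % self.n_conditions
            arr[g, idx] = self.signature_onset
        return arr

    def log_hr(self) -> np.ndarray:
        """Per-pattern log hazard ratios, columns ordered as OUTCOMES."""
        if self.hazard_log_hr is not None:
            arr = np.asarray(self.hazard_log_hr, dtype=float)
            if arr.shape != (self.n_patterns_true, len(OUTCOMES)):
                raise ValueError("hazard_log_hr must be (n_patterns_true, 3)")
            return arr
        col = np.linspace(0.0, 1.2, self.n_patterns_true)
        return np.tile(col[:, None], (1, len(OUTCOMES)))

    def validate(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if self.study_start > self.study_end:
            raise ValueError("study_start must not exceed study_end")
        if self.n_patterns_true < 1:
            raise ValueError("n_patterns_true must be >= 1")
        load = self.loadings()
        if ((load < 0) | (load > 1)).any():
            raise ValueError("condition loadings must be probabilities in [0, 1]")
        for p in (self.baseline_onset, self.censoring_rate, self.baseline_fraction,
                  self.female_fraction, self.deprivation_missing):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not np.isfinite(self.log_hr()).all():
            raise ValueError("hazard log-HRs must be finite")
        for o in OUTCOMES:
            if self.baseline_hazard[o] < 0 or not np.isfinite(self.deficit_log_hr.get(o, 0.0)):
                raise ValueError("hazards must be finite and non-negative")


def _onset_prob(loadings: np.ndarray, age_slope: float, ages: np.ndarray) -> np.ndarray:
    """Onset probability (n_ages, G, C) at each age, clamped at {0, 1} loadings."""
    with np.errstate(divide="ignore"):
        base = logit(loadings)  # (G, C); +-inf at 0/1 is intended
    lp = base[None, :, :] + age_slope * (ages[:, None, None] - 65.0)
    return expit(lp)


def simulate_cohort(
    config: ScenarioConfig,
) -> tuple[Cohort, pd.DataFrame]:
    """Simulate a dynamic cohort; return (cohort, ground_truth).

    ``ground_truth`` has one row per person-year with the planted pattern
    (constant over a person's follow-up) so that recovered cluster labels
    can be scored against it.  Reproducible: the same config (including
    seed) yields an identical cohort.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n, G, C, D = (config.n_persons, config.n_patterns_true,
                  config.n_conditions, config.n_deficits)
    years = np.arange(config.study_start, config.study_end + 1)

    person_id = np.array([f"p{i:06d}" for i in range(n)])
    pattern = rng.integers(G, size=n)
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    deprivation = rng.integers(1, 6, size=n).astype(float)
    deprivation[rng.random(n) < config.deprivation_missing] = np.nan

    at_baseline = rng.random(n) < config.baseline_fraction
    if config.study_end == config.study_start:
        at_baseline[:] = True
    entry_year = np.where(
        at_baseline,
        config.study_start,
        rng.integers(config.study_start + 1, config.study_end + 1, size=n),
    )
    # both baseline members and later entrants (turning 65 or arriving in
    # the catchment area already aged 65+) draw the same entry-age profile
    entry_age = np.minimum(
        65 + np.floor(rng.exponential(config.entry_age_scale, size=n)).astype(int),
        99,
    )

    loadings = config.loadings()
    ages_axis = np.arange(65, AGE_MAX + 1)
    p_onset = _onset_prob(loadings, config.age_slope, ages_axis)  # (A, G, C)

    # burn-in: probability a condition is already active on entry, from
    # accumulated onset risk between age 65 and the year before entry
    with np.errstate(divide="ignore"):
        log_surv = np.log1p(-np.clip(p_onset, 0, 1 - 1e-15))
    cum_log_surv = np.concatenate(
        [np.zeros((1, G, C)), np.cumsum(log_surv, axis=0)], axis=0
    )  # index a: survival through ages 65..65+a-1
    burn = entry_age - 65
    p_active0 = 1.0 - np.exp(cum_log_surv[burn, pattern, :])  # (n, C)
    active = rng.random((n, C)) < p_active0

    log_hr = config.log_hr()
    base_h = np.array([config.baseline_hazard[o] for o in OUTCOMES])
    def_coef = np.array([config.deficit_log_hr.get(o, 0.0) for o in OUTCOMES])

    exited = np.zeros(n, dtype=bool)
    exit_year = np.full(n, config.study_end)
    exit_reason = np.full(n, "study_end", dtype=object)
    event_year = {o: np.full(n, -1) for o in OUTCOMES}

    rows: list[pd.DataFrame] = []
    for y in years:
        alive = (~exited) & (entry_year <= y)
        if not alive.any():
            continue
        idx = np.flatnonzero(alive)
        age = entry_age[idx] + (y - entry_year[idx])
        g = pattern[idx]

        # condition onset this calendar year (status at Dec 31)
        p = p_onset[age - 65, g, :]
        new = (~active[idx]) & (rng.random((len(idx), C)) < p)
        active[idx] |= new
        ncond = active[idx].sum(axis=1)

        # deficit count and uniformly chosen deficits given the count
        p_def = expit(
            config.deficit_intercept
            + config.deficit_cond_coef * ncond
            + config.deficit_age_coef * (age - 65)
        )
        ndef = rng.binomial(D, p_def)
        order = np.argsort(rng.random((len(idx), D)), axis=1)
        ranks = np.empty_like(order)
        np.put_along_axis(ranks, order, np.arange(D)[None, :].repeat(len(idx), 0), axis=1)
        deficits = (ranks < ndef[:, None]).astype(np.int8)

        # annual outcome events
        h = base_h[None, :] * np.exp(log_hr[g, :] + def_coef[None, :] * ndef[:, None])
        p_event = 1.0 - np.exp(-h)
        draws = rng.random((len(idx), len(OUTCOMES))) < p_event
        died = draws[:, 0]
        for j, o in enumerate(OUTCOMES):
            if o == "death":
                hit = died
            else:
                hit = draws[:, j] & ~died & (event_year[o][idx] < 0)
            event_year[o][idx[hit]] = y
        censored = (rng.random(len(idx)) < config.censoring_rate) & ~died

        nh_flag = (event_year["nursing_home"][idx] >= 0) & (
            event_year["nursing_home"][idx] <= y
        )
        hc_flag = (event_year["home_care"][idx] >= 0) & (
            event_year["home_care"][idx] <= y
        )
        frame = pd.DataFrame({
            "person_id": person_id[idx],
            "year": y,
            "age": age,
            "sex": sex[idx],
            "deprivation": deprivation[idx],
            "nh_flag": nh_flag.astype(np.int8),
            "hc_flag": hc_flag.astype(np.int8),
        })
        cond_cols = pd.DataFrame(
            active[idx].astype(np.int8),
            columns=[f"cond_c{k + 1:02d}" for k in range(C)],
            index=frame.index,
        )
        def_cols = pd.DataFrame(
            deficits, columns=[f"def_d{k + 1:02d}" for k in range(D)], index=frame.index
        )
        rows.append(pd.concat([frame, cond_cols, def_cols], axis=1))

        gone = died | censored
        exited[idx[gone]] = True
        exit_year[idx[gone]] = y
        exit_reason[idx[died]] = "death"
        exit_reason[idx[censored & ~died]] = "lost_to_followup"

    records = pd.concat(rows, ignore_index=True)
    records = records.sort_values(["person_id", "year"], kind="mergesort").reset_index(drop=True)

    tl = pd.DataFrame({
        "person_id": person_id,
        "entry_year": entry_year,
        "exit_year": exit_year,
        "exit_reason": exit_reason,
    })
    for o, col in (("death", "death_year"), ("nursing_home", "nh_year"), ("home_care", "hc_year")):
        v = event_year[o].astype(float)
        v[v < 0] = np.nan
        tl[col] = pd.array(v, dtype="Int64")
    tl = tl[tl["person_id"].isin(records["person_id"])].reset_index(drop=True)

    conditions = ConditionCatalog(tuple(f"c{k + 1:02d}" for k in range(C)))
    n_dis = min(20, D)
    deficit_cat = DeficitCatalog(
        tuple(f"d{k + 1:02d}" for k in range(D)),
        tuple(k < n_dis for k in range(D)),
    )
    cohort = Cohort(records, tl, conditions, deficit_cat)
    cohort.validate()

    truth_person = pd.DataFrame({"person_id": person_id, "pattern": pattern})
    truth = records[["person_id", "year"]].merge(truth_person, on="person_id")
    truth = truth.rename(columns={"pattern": "true_pattern"})
    return cohort, truth


def summarize_cohort(cohort: Cohort) -> dict[str, pd.DataFrame]:
    """Descriptive table on each person's first and last year of follow-up.

    Returns ``{"characteristics": ..., "condition_prevalence": ...}``; the
    characteristics table mirrors the usual first/last-year cohort
    description (age median/IQR, % multimorbid, condition-count bands,
    frailty categories, outcome flags).
    """
    from mmtraj.status import frailty_category, multimorbidity_band

    rec = cohort.records
    if rec.empty:
        raise EmptyCohortError("cannot summarize an empty cohort")
    cond_cols, def_cols = cohort.condition_columns, cohort.deficit_columns
    srt = rec.sort_values(["person_id", "year"])
    blocks = {}
    for name, sub in (
        ("first_year", srt.groupby("person_id", sort=False).head(1)),
        ("last_year", srt.groupby("person_id", sort=False).tail(1)),
    ):
        ncond = sub[cond_cols].sum(axis=1)
        ndef = sub[def_cols].sum(axis=1)
        cat = frailty_category(ndef.to_numpy(), cohort.deficits.size)
        band = multimorbidity_band(ncond.to_numpy())
        stats = {
            "n": len(sub),
            "age_median": sub["age"].median(),
            "age_q1": sub["age"].quantile(0.25),
            "age_q3": sub["age"].quantile(0.75),
            "pct_female": 100.0 * (sub["sex"] == "female").mean(),
            "conditions_median": ncond.median(),
            "deficits_median": ndef.median(),
            "pct_multimorbid": 100.0 * (ncond >= 2).mean(),
            "pct_nursing_home": 100.0 * sub["nh_flag"].mean(),
            "pct_home_care": 100.0 * sub["hc_flag"].mean(),
        }
        for b in ("0-1", "2-5", "6-10", ">10"):
            stats[f"pct_band_{b}"] = 100.0 * (band == b).mean()
        for f in ("fit", "mild", "moderate", "severe"):
            stats[f"pct_{f}"] = 100.0 * (cat == f).mean()
        blocks[name] = stats
    characteristics = pd.DataFrame(blocks)

    per_year = rec.groupby("year")[cond_cols].mean()
    prevalence = pd.DataFrame({
        "condition": cohort.conditions.codes,
        "mean_annual_prevalence": per_year.mean(axis=0).to_numpy(),
        "pooled_prevalence": rec[cond_cols].mean().to_numpy(),
    })
    return {"characteristics": characteristics, "condition_prevalence": prevalence}
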