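import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from mmtraj.simulate import ScenarioConfig, simulate_cohort
from mmtraj.survival import (
    NoFitError,
    build_counting_process,
    compare_variants,
    fit_cause_specific,
    fit_cox_timevarying,
)


def _timeline(person, entry, exit_, reason="study_end", death=None, nh=None, hc=None):
    return {"person_id": person, "entry_year": entry, "exit_year": exit_,
            "exit_reason": reason, "death_year": death, "nh_year": nh,
            "hc_year": hc}


def _assign(person, years, patterns):
    return pd.DataFrame({"person_id": person, "year": list(years),
                         "pattern": patterns, "membership": 1.0})


def test_counting_process_shapes():
    a = pd.concat([
        _assign("surv", range(2010, 2013), ["A"] * 3),
        _assign("dead", range(2010, 2012), ["A", "B"]),
        _assign("fast", [2010], ["B"]),
    ])
    tl = pd.DataFrame([
        _timeline("surv", 2010, 2012),
        _timeline("dead", 2010, 2011, "death", death=2011),
        _timeline("fast", 2010, 2010, "death", death=2010),
    ])
    t = build_counting_process(a, tl, "death")
    surv = t[t["person_id"] == "surv"]
    assert len(surv) == 3 and surv["event"].sum() == 0
    dead = t[t["person_id"] == "dead"]
    assert len(dead) == 2 and dead["event"].tolist() == [0, 1]
    fast = t[t["person_id"] == "fast"]
    assert len(fast) == 1
    assert (fast[["t_start", "t_stop", "event"]].to_numpy() == [[0, 1, 1]]).all()


def test_counting_process_censors_nonfatal_outcome_at_event_and_death():
    a = _assign("p", range(2010, 2015), ["A"] * 5)
    tl = pd.DataFrame([_timeline("p", 2010, 2014, nh=2012)])
    t = build_counting_process(a, tl, "nursing_home")
    assert len(t) == 3 and t["event"].tolist() == [0, 0, 1]
    # death censors without an event row
    tl2 = pd.DataFrame([_timeline("q", 2010, 2012, "death", death=2012)])
    a2 = _assign("q", range(2010, 2013), ["A"] * 3)
    t2 = build_counting_process(a2, tl2, "nursing_home")
    assert len(t2) == 3 and t2["event"].sum() == 0


def test_counting_process_person_time_conservation(small_cohort, truth_assignments):
    cohort, _ = small_cohort
    t = build_counting_process(truth_assignments, cohort.timelines, "death")
    tl = cohort.timelines
    expected = (tl["exit_year"] - tl["entry_year"] + 1).sum()
    assert (t["t_stop"] - t["t_start"]).sum() == expected


def test_event_before_entry_rejected():
    a = _assign("p", range(2012, 2014), ["A", "A"])
    tl = pd.DataFrame([_timeline("p", 2012, 2013, nh=2010)])
    with pytest.raises(ValueError, match="before cohort entry"):
        build_counting_process(a, tl, "nursing_home")


def _efron_mle(table):
    """Independent Efron partial-likelihood maximizer (dense oracle)."""
    X = pd.get_dummies(table["pattern"], prefix="p").iloc[:, 1:].astype(float).to_numpy()
    ts = table["t_start"].to_numpy()
    tp = table["t_stop"].to_numpy()
    ev = table["event"].to_numpy().astype(bool)

    def nll(beta):
        lp = X @ beta
        w = np.exp(lp)
        ll = 0.0
        for t in np.unique(tp[ev]):
            R = (ts < t) & (t <= tp)
            D = ev & (tp == t)
            d = D.sum()
            sw, swd = w[R].sum(), w[D].sum()
            ll += lp[D].sum()
            ll -= sum(np.log(sw - (j / d) * swd) for j in range(d))
        return -ll

    res = minimize(nll, np.zeros(X.shape[1]), method="BFGS", tol=1e-12)
    return res.x, -res.fun


def test_time_constant_fit_matches_standard_cox_oracle():
    cohort, truth = simulate_cohort(
        ScenarioConfig(n_persons=300, n_patterns_true=3, seed=31))
    a = truth.rename(columns={"true_pattern": "pattern"})
    table = build_counting_process(a, cohort.timelines, "death")
    fit = fit_cox_timevarying(table, 0, outcome="death")
    beta_oracle, ll_oracle = _efron_mle(table)
    beta_fit = np.log(fit.hazard_ratios.set_index("pattern")["hr"].loc[[1, 2]])
    np.testing.assert_allclose(beta_fit, beta_oracle, atol=1e-6)
    assert fit.log_likelihood == pytest.approx(ll_oracle, abs=1e-6)


def test_null_likelihood_consistency():
    """2 * (ll - ll0) must reproduce the LR statistic, and ll0 must equal the
    independent Efron likelihood at beta = 0."""
    cohort, truth = simulate_cohort(
        ScenarioConfig(n_persons=250, n_patterns_true=2, seed=37))
    a = truth.rename(columns={"true_pattern": "pattern"})
    table = build_counting_process(a, cohort.timelines, "death")
    fit = fit_cox_timevarying(table, 0)
    assert 2 * (fit.log_likelihood - fit.null_log_likelihood) == pytest.approx(
        fit.lr_statistic, abs=1e-8)
    X = pd.get_dummies(table["pattern"], prefix="p").iloc[:, 1:].astype(float).to_numpy()
    ts, tp, ev = (table["t_start"].to_numpy(), table["t_stop"].to_numpy(),
                  table["event"].to_numpy().astype(bool))
    ll0 = 0.0
    for t in np.unique(tp[ev]):
        R = ((ts < t) & (t <= tp)).sum()
        d = (ev & (tp == t)).sum()
        ll0 -= sum(np.log(R - j) for j in range(d))
    assert fit.null_log_likelihood == pytest.approx(ll0, abs=1e-6)


def test_exchangeable_patterns_give_unit_hazard_ratio():
    rng = np.random.default_rng(41)
    rows, tls = [], []
    for i in range(300):
        death = rng.random() < 0.3
        length = rng.integers(1, 6)
        years = list(range(2010, 2010 + length))
        for pat in ("A", "B"):          # identical event process in both
            pid = f"p{i}{pat}"
            rows.append(_assign(pid, years, [pat] * length))
            tls.append(_timeline(pid, 2010, years[-1],
                                 "death" if death else "study_end",
                                 death=years[-1] if death else None))
    a = pd.concat(rows)
    tl = pd.DataFrame(tls)
    fit = fit_cox_timevarying(build_counting_process(a, tl, "death"), "A")
    row = fit.hazard_ratios.set_index("pattern").loc["B"]
    assert row["hr"] == pytest.approx(1.0, abs=1e-6)
    assert row["ci_low"] < 1.0 < row["ci_high"]


def test_degenerate_tables_raise_no_fit():
    a = _assign("p", range(2010, 2013), ["A"] * 3)
    tl = pd.DataFrame([_timeline("p", 2010, 2012)])
    table = build_counting_process(a, tl, "death")
    with pytest.raises(NoFitError):
        fit_cox_timevarying(table, "A")           # zero events
    a2 = pd.concat([a, _assign("q", [2010], ["A"])])
    tl2 = pd.DataFrame([_timeline("p", 2010, 2012),
                        _timeline("q", 2010, 2010, "death", death=2010)])
    with pytest.raises(NoFitError):                # single pattern level
        fit_cox_timevarying(build_counting_process(a2, tl2, "death"), "A")


def test_cause_specific_equals_plain_fit_without_deaths():
    rng = np.random.default_rng(43)
    rows, tls = [], []
    for i in range(400):
        pat = "A" if i % 2 == 0 else "B"
        nh = rng.random() < (0.2 if pat == "B" else 0.1)
        length = int(rng.integers(2, 6))
        years = list(range(2010, 2010 + length))
        tls.append(_timeline(f"p{i}", 2010, years[-1],
                             nh=years[-1] if nh else None))
        rows.append(_assign(f"p{i}", years, [pat] * length))
    a, tl = pd.concat(rows), pd.DataFrame(tls)
    t_nh = build_counting_process(a, tl, "nursing_home")
    t_death = build_counting_process(a, tl, "death")
    cs = fit_cause_specific(t_nh, t_death, "A", outcome="nursing_home")
    plain = fit_cox_timevarying(t_nh, "A", outcome="nursing_home")
    pd.testing.assert_frame_equal(cs.hazard_ratios, plain.hazard_ratios)


def test_cause_specific_all_die_first_year_gives_no_fit():
    tls, rows = [], []
    for i in range(20):
        rows.append(_assign(f"p{i}", [2010], ["A" if i % 2 else "B"]))
        tls.append(_timeline(f"p{i}", 2010, 2010, "death", death=2010))
    a, tl = pd.concat(rows), pd.DataFrame(tls)
    t_nh = build_counting_process(a, tl, "nursing_home")
    with pytest.raises(NoFitError):
        fit_cause_specific(t_nh, build_counting_process(a, tl, "death"), "A")


def test_schoenfeld_and_concordance_are_reported(small_cohort, truth_assignments):
    cohort, _ = small_cohort
    table = build_counting_process(truth_assignments, cohort.timelines, "death")
    fit = fit_cox_timevarying(table, 0)
    assert 0.5 <= fit.cindex <= 1.0
    assert all(0 <= p <= 1 or np.isnan(p) for p in fit.schoenfeld_p.values())
    assert fit.aic == pytest.approx(-2 * fit.log_likelihood
                                    + 2 * len(fit.schoenfeld_p))


def test_compare_variants_ties_and_errors(small_cohort, truth_assignments):
    cohort, _ = small_cohort
    table = build_counting_process(truth_assignments, cohort.timelines, "death")
    fit = fit_cox_timevarying(table, 0, outcome="death", variant="age")
    comp = compare_variants({"death": fit}, {"death": fit})
    assert (comp["better"] == "tie").all()
    with pytest.raises(ValueError, match="outcomes"):
        compare_variants({"death": fit}, {})
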