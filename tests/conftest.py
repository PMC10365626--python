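import numpy as np
import pandas as pd
import pytest

from mmtraj.simulate import ScenarioConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Small default-structure cohort shared by read-only tests."""
    cfg = ScenarioConfig(n_persons=300, seed=11)
    cohort, truth = simulate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def truth_assignments(small_cohort):
    """Planted patterns used as (perfect) per-year assignments."""
    _, truth = small_cohort
    a = truth.rename(columns={"true_pattern": "pattern"}).copy()
    a["membership"] = 1.0
    return a


@pytest.fixture()
def toy_cohort_csv(tmp_path):
    """One person followed 2010-2012, dying in 2012; 3 conditions, 2 deficits."""
    cond = {f"cond_c{i}": [0, 1, 1] for i in (1,)}
    cond.update({f"cond_c{i}": [0, 0, 1] for i in (2,)})
    cond.update({f"cond_c{i}": [0, 0, 0] for i in (3,)})
    rec = pd.DataFrame({
        "person_id": ["a"] * 3,
        "year": [2010, 2011, 2012],
        "age": [70, 71, 72],
        "sex": ["female"] * 3,
        "deprivation": [2, 2, 2],
        "nh_flag": [0, 0, 0],
        "hc_flag": [0, 0, 0],
        **cond,
        "def_d1": [0, 1, 1],
        "def_d2": [0, 0, 1],
    })
    events = pd.DataFrame({
        "person_id": ["a"], "entry_year": [2010], "exit_year": [2012],
        "exit_reason": ["death"], "death_year": [2012],
        "nh_year": [pd.NA], "hc_year": [pd.NA],
    })
    rec_path = tmp_path / "cohort.csv"
    ev_path = tmp_path / "events.csv"
    rec.to_csv(rec_path, index=False)
    events.to_csv(ev_path, index=False)
    return rec_path, ev_path
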