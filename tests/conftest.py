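import os

# deterministic linear algebra: a fixed single-threaded reduction order
# makes seeded MCMC paths identical across machines with different core
# counts (must run before numpy is first imported)
for _v in ("OPENBLAS_NUM_THREADS", "OMP_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_v, "1")

import numpy as np
import pandas as pd
import pytest

import famliab as fl


def make_cohort_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["person_id", "family_id", "role", "sex", "age", "county_id",
                 "dx_code_count"],
    )


@pytest.fixture
def tiny_frame():
    """Two families (2 and 3 children is overkill; use 1 and 2), two counties."""
    return make_cohort_frame([
        ("p1", "f1", "father", "male", 45, "c1", 0),
        ("p2", "f1", "mother", "female", 44, "c1", 2),
        ("p3", "f1", "child", "male", 18, "c1", 0),
        ("p4", "f1", "child", "female", 20, "c1", 1),
        ("p5", "f2", "father", "male", 50, "c2", 0),
        ("p6", "f2", "mother", "female", 51, "c2", 0),
        ("p7", "f2", "child", "female", 17, "c2", 3),
    ])


@pytest.fixture
def tiny_cohort(tiny_frame):
    return fl.Cohort(tiny_frame)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated cohort shared by read-only tests."""
    truth = fl.TruthConfig(n_families=400, n_counties=30,
                           sigma2={"h": 0.5, "e": 0.5}, seed=7)
    cohort, eqi_table, meta = fl.simulate_cohort(truth)
    return truth, cohort, eqi_table, meta
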