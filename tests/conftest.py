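import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import dentage as d

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort (80 + 80 cases) for fast model tests."""
    return d.generate_cohort(d.CohortParams(n_female=80, n_male=80, seed=11))


@pytest.fixture(scope="session")
def small_xy(small_cohort):
    X, y = d.design_matrix(small_cohort, include_sex=True)
    return X, y


@pytest.fixture(scope="session")
def small_split(small_xy):
    X, _ = small_xy
    return d.split_cohort(list(X.index), seed=11)


@pytest.fixture(scope="session")
def small_model(small_xy, small_split):
    X, y = small_xy
    tr = list(small_split.train_ids)
    return d.fit_rbf(X.loc[tr], y.loc[tr], H=10, seed=11)


@pytest.fixture()
def complete_landmark_set():
    """One complete 36-point landmark set realizing mid-childhood ratios."""
    df = d.generate_cohort(d.CohortParams(n_female=1, n_male=0, seed=5))
    row = df.iloc[0]
    vals = {n: row[n] for n in d.INDICATOR_NAMES}
    return d.generate_landmarks(
        vals, case_id="p001", sex="F", age_months=int(row["age_months"])
    )


@pytest.fixture()
def tiny_regression():
    """Small deterministic regression problem (n=12, d=3, distinct rows)."""
    rng = np.random.default_rng(42)
    X = pd.DataFrame(
        rng.uniform(0.5, 2.0, size=(12, 3)),
        columns=["a", "b", "c"],
        index=[f"c{i:02d}" for i in range(12)],
    )
    y = pd.Series(
        60.0 + 40.0 * X["a"].to_numpy() + rng.normal(0, 1.0, 12), index=X.index
    )
    return X, y
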