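"""Shared fixtures: small synthetic cohorts and models built at test time."""

import numpy as np
import pandas as pd
import pytest

import graybn as gb


def cohort_from_matrix(X, roi_names, groups, seed=0):
    """Wrap a (n, d) matrix plus a per-row group label list as a CohortTable."""
    rng = np.random.default_rng(seed)
    n = len(X)
    df = pd.DataFrame(np.asarray(X, float), columns=list(roi_names))
    df.insert(0, "subject_id", [f"s{i:04d}" for i in range(n)])
    df.insert(1, "group", list(groups))
    df.insert(2, "sex", rng.choice(["F", "M"], size=n))
    df.insert(3, "age", np.round(rng.uniform(20, 90, size=n), 1))
    return gb.CohortTable(df, roi_names=tuple(roi_names))


def two_group_cohort(model_a, model_b, n_a, n_b, labels=("young", "old"), seed=0):
    """Sample one group per model (raw scale) and stack into a cohort."""
    ss = np.random.SeedSequence(seed)
    ca, cb = ss.spawn(2)
    Xa = model_a.sample(n_a, seed=np.random.default_rng(ca), raw=True)
    Xb = model_b.sample(n_b, seed=np.random.default_rng(cb), raw=True)
    X = np.vstack([Xa, Xb])
    groups = [labels[0]] * n_a + [labels[1]] * n_b
    return cohort_from_matrix(X, model_a.nodes, groups, seed=seed + 1)


@pytest.fixture(scope="session")
def default_cohort():
    """The study-conditions synthetic cohort: 109 young + 82 old subjects."""
    return gb.make_cohort(gb.default_spec(seed=11))


@pytest.fixture(scope="session")
def young_model():
    return gb.make_group_model(gb.default_spec().groups[0])


@pytest.fixture(scope="session")
def old_model():
    return gb.make_group_model(gb.default_spec().groups[1])


@pytest.fixture(scope="session")
def generator_group_models(young_model, old_model):
    """GroupModels wrapping the two generating networks directly."""
    return gb.GroupModels(
        labels=("young", "old"),
        results={
            "young": gb.GaussianBNResults(None, young_model),
            "old": gb.GaussianBNResults(None, old_model),
        },
    )
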