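import warnings

import numpy as np
import pytest

import hipmsm as hm


@pytest.fixture(scope="session")
def structure():
    return hm.default_structure()


@pytest.fixture(scope="session")
def truth3():
    """Comorbidity-only generating truth (obesity, dm, cvd + age-65 shift)."""
    return hm.comorbidity_only_truth()


@pytest.fixture(scope="session")
def small_cohort(truth3):
    """A small deterministic synthetic cohort for likelihood/fitting tests."""
    cfg = hm.CohortConfig(n_subjects=80, seed=5, truth=truth3)
    df, _ = hm.generate_cohort(cfg)
    return hm.dataframe_to_cohort(df)


@pytest.fixture(scope="session")
def small_panel(truth3):
    cfg = hm.CohortConfig(n_subjects=80, seed=5, truth=truth3)
    df, _ = hm.generate_cohort(cfg)
    return df


def random_generator(rng, n=5, absorbing=(4,), low=0.01, high=0.5):
    """A random valid generator matrix on n states (helper for oracles)."""
    Q = rng.uniform(low, high, size=(n, n))
    np.fill_diagonal(Q, 0.0)
    for a in absorbing:
        Q[a] = 0.0
    Q[np.arange(n), np.arange(n)] = -Q.sum(axis=1)
    return Q


def fit_quiet(*args, **kwargs):
    """fit_mle with initialization warnings silenced (sparse tiny cohorts)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return hm.fit_mle(*args, **kwargs)
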