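import numpy as np
import pytest

from hte_recommender.cohorts import assign_cohorts
from hte_recommender.config import CATEGORIES
from hte_recommender.hte import build_feature_matrix
from hte_recommender.outcomes import apply_eligibility, compute_outcome
from hte_recommender.synthetic import SimConfig, generate_cohort

# Lighter learners for tests that only need plumbing, not statistical power.
FAST_MODEL = {
    "outcome_learner": {"max_iter": 40, "max_depth": 3, "learning_rate": 0.2},
    "propensity_learner": {"max_iter": 40, "max_depth": 3, "learning_rate": 0.2},
    "cate_learner": {"n_estimators": 60, "min_samples_leaf": 20},
}


@pytest.fixture(scope="session")
def cohort():
    """A medium synthetic cohort shared (read-only) across tests."""
    return generate_cohort(SimConfig(n_members=800, seed=101))


@pytest.fixture(scope="session")
def eligible(cohort):
    """(members, outcomes) for the eligible subset of the shared cohort."""
    outcomes = [compute_outcome(m) for m in cohort]
    retained, _ = apply_eligibility(cohort, outcomes)
    by_id = {o.member_id: o for o in outcomes}
    return retained, [by_id[m.member_id] for m in retained]


@pytest.fixture(scope="session")
def model_inputs(eligible):
    """(members, X, Y, assignments) ready for DR fitting."""
    members, outcomes = eligible
    X, _ = build_feature_matrix(members, outcomes)
    Y = np.array([o.outcome_y for o in outcomes])
    assignments = assign_cohorts(members)
    return members, X, Y, assignments


@pytest.fixture
def toy_uplift_table():
    """8 members (4 treated, 4 control) with hand-assigned scores and Y."""
    scores = np.array([8.0, 7.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
    T = np.array([1, 0, 1, 0, 1, 0, 1, 0])
    Y = np.array([-2.0, -0.5, -1.5, -1.0, 0.0, -0.2, 0.5, -0.8])
    return scores, T, Y


@pytest.fixture(scope="session")
def categories():
    return CATEGORIES
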