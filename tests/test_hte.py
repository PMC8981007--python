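"""DR learner: pseudo-outcomes, cross-fitting, feature matrix, determinism."""

import numpy as np
import pandas as pd
import pytest

from hte_recommender.hte import (
    FitError,
    build_feature_matrix,
    dr_pseudo_outcome,
    fit_dr_learner,
    predict_cate,
)

from conftest import FAST_MODEL


def brute_force_aipw(y, t, g1, g0, p):
    """Independent oracle: the AIPW pseudo-outcome, one row at a time."""
    out = []
    for yi, ti, g1i, g0i, pi in zip(y, t, g1, g0, p):
        direct = g1i - g0i
        if ti == 1:
            correction = (yi - g1i) / pi
        else:
            correction = -(yi - g0i) / (1.0 - pi)
        out.append(direct + correction)
    return np.array(out)


class TestPseudoOutcome:
    def test_hand_values(self):
        # treated: (0.5-0.2) + (1.0-0.5)/0.5 = 1.3
        assert dr_pseudo_outcome(1.0, 1, 0.5, 0.2, 0.5) == pytest.approx(1.3)
        # control: 0.3 - (0.0-0.2)/0.5 = 0.7
        assert dr_pseudo_outcome(0.0, 0, 0.5, 0.2, 0.5) == pytest.approx(0.7)

    def test_zero_residual_identity(self):
        for p in (0.1, 0.5, 0.9):
            assert dr_pseudo_outcome(0.5, 1, 0.5, 0.2, p) == pytest.approx(0.3)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        n = 64
        y = rng.normal(size=n)
        t = rng.integers(0, 2, size=n)
        g1, g0 = rng.normal(size=n), rng.normal(size=n)
        p = rng.uniform(0.05, 0.95, size=n)
        psi = dr_pseudo_outcome(y, t, g1, g0, p)
        assert np.max(np.abs(psi - brute_force_aipw(y, t, g1, g0, p))) < 1e-12

    def test_clipping_and_invalid_p(self):
        psi = dr_pseudo_outcome(1.0, 1, 0.0, 0.0, 0.001, clip_bounds=(0.01, 0.99))
        assert psi == pytest.approx(1.0 / 0.01)
        with pytest.raises(ValueError):
            dr_pseudo_outcome(1.0, 1, 0.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            dr_pseudo_outcome(1.0, 1, 0.0, 0.0, 0.5, clip_bounds=(0.0, 1.0))


class TestFeatureMatrix:
    def test_one_hot_expansion_and_fixed_order(self, eligible):
        members, outcomes = eligible
        X, names = build_feature_matrix(members, outcomes)
        assert list(X.columns) == names
        assert X.notna().all().all()
        # every categorical level observed in the cohort becomes a column
        genders = {m.covariates["gender"] for m in members}
        assert {f"gender_{g}" for g in genders} <= set(names)
        # determinism: same inputs, same matrix
        X2, names2 = build_feature_matrix(members, outcomes)
        assert names2 == names and np.array_equal(X.to_numpy(), X2.to_numpy())

    def test_identical_members_identical_rows(self, eligible):
        members, outcomes = eligible
        dup = [members[0], members[0]]
        X, _ = build_feature_matrix(dup, [outcomes[0], outcomes[0]])
        assert np.array_equal(X.iloc[0].to_numpy(), X.iloc[1].to_numpy())

    def test_column_means_match_configured_covariates(self, eligible):
        members, _ = eligible
        X, _ = build_feature_matrix(members)
        # age ~ Normal(54, 10): the cohort mean should sit near 54
        assert abs(X["age"].mean() - 54.0) < 3 * 10.0 / np.sqrt(len(X))


class TestFitDRLearner:
    def test_single_cohort_is_a_fit_error(self):
        X = np.random.default_rng(1).normal(size=(40, 3))
        with pytest.raises(FitError):
            fit_dr_learner(X, np.ones(40, dtype=int), np.zeros(40))

    def test_report_shapes_and_split_ratio(self, model_inputs):
        _, X, Y, assignments = model_inputs
        T = np.array([int(a.flags["coaching"]) for a in assignments])
        model, report = fit_dr_learner(
            X, T, Y, seed=3, category="coaching", model_config=FAST_MODEL
        )
        n = len(Y)
        assert report.n_train + report.n_validation == n
        assert report.n_train == pytest.approx(0.65 * n, abs=1)
        assert np.isfinite(report.validation_mse)
        assert len(model.tau_validation) == report.n_validation

    def test_seed_determinism(self, model_inputs):
        _, X, Y, assignments = model_inputs
        T = np.array([int(a.flags["content"]) for a in assignments])
        m1, _ = fit_dr_learner(X, T, Y, seed=9, model_config=FAST_MODEL)
        m2, _ = fit_dr_learner(X, T, Y, seed=9, model_config=FAST_MODEL)
        assert np.array_equal(m1.train_index, m2.train_index)
        assert np.array_equal(m1.tau_validation, m2.tau_validation)

    def test_degenerate_features_give_constant_cate(self):
        """All-constant X: tau_hat collapses to a single DR ATE value."""
        rng = np.random.default_rng(5)
        n = 400
        X = np.ones((n, 2))
        T = rng.integers(0, 2, size=n)
        Y = rng.normal(-1.0 * T, 1.0)
        model, _ = fit_dr_learner(X, T, Y, seed=1, model_config=FAST_MODEL)
        tau = np.concatenate([model.tau_train, model.tau_validation])
        assert np.ptp(tau) < 1e-9
        # the constant equals the DR ATE up to forest bootstrap resampling
        psi = model.psi_train
        assert tau.mean() == pytest.approx(
            psi.mean(), abs=3 * psi.std(ddof=1) / np.sqrt(len(psi))
        )

    def test_predict_cate_determinism_and_schema(self, model_inputs):
        _, X, Y, assignments = model_inputs
        T = np.array([int(a.flags["nutrition"]) for a in assignments])
        model, _ = fit_dr_learner(X, T, Y, seed=2, model_config=FAST_MODEL)
        est = predict_cate(model, X, category="nutrition")
        assert len(est) == len(X)
        again = model.predict(X)
        assert np.array_equal([e.tau_hat for e in est], again)
        with pytest.raises(ValueError):
            model.predict(X.iloc[:, :-1])
        shuffled = X[[X.columns[-1], *X.columns[:-1]]]
        with pytest.raises(ValueError):
            model.predict(shuffled)
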