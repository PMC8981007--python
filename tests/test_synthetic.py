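"""Generator correctness: determinism, ground truth, confounding, SMBG means."""

import math

import numpy as np
import pytest

from hte_recommender.config import ADAG_SLOPE, CATEGORIES
from hte_recommender.synthetic import (
    ConfigurationError,
    SimConfig,
    cohort_frames,
    generate_cohort,
    members_from_frames,
    true_cate,
)

ZERO_EFFECTS = {c: {"intercept": 0.0} for c in CATEGORIES}


def test_empty_cohort():
    assert generate_cohort(SimConfig(n_members=0, seed=1)) == []


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError):
        SimConfig(n_members=-1)
    with pytest.raises(ConfigurationError):
        SimConfig(noise_sd=-0.1)
    with pytest.raises(ConfigurationError):
        SimConfig(effect_fn_coefs={"coaching": {"intercept": 0.0}})


def test_seed_determinism_and_substream_stability():
    a = generate_cohort(SimConfig(n_members=40, seed=7))
    b = generate_cohort(SimConfig(n_members=40, seed=7))
    fa, fb = cohort_frames(a), cohort_frames(b)
    for x, y in zip(fa, fb):
        assert x.equals(y)
    # Growing the cohort must not reshuffle existing members.
    big = generate_cohort(SimConfig(n_members=60, seed=7))
    assert cohort_frames(big[:40])[0].equals(fa[0])
    # A different seed produces different members.
    other = generate_cohort(SimConfig(n_members=40, seed=8))
    assert not cohort_frames(other)[0].equals(fa[0])


def test_record_invariants(cohort):
    for m in cohort:
        assert all(d >= 0 for d, _ in m.smbg_readings)
        assert all(v >= 0 for v in m.engagement.values())
        assert 0.0 <= m.engagement["nutrition_nudge_yes_frac"] <= 1.0
        assert 0.0 <= m.engagement["content_nudge_yes_frac"] <= 1.0
        assert set(m.true_cate) == set(CATEGORIES)


def test_true_cate_lookup(cohort):
    m = cohort[0]
    assert true_cate(m, "coaching") == m.true_cate["coaching"]
    with pytest.raises(KeyError):
        true_cate(m, "yoga")
    null = generate_cohort(SimConfig(n_members=3, seed=2, effect_fn_coefs=ZERO_EFFECTS))
    assert all(true_cate(m, c) == 0.0 for m in null for c in CATEGORIES)


def test_effect_function_hand_evaluated():
    """tau(x) equals the linear predictor on standardized covariates."""
    cfg = SimConfig(
        n_members=5,
        seed=3,
        effect_fn_coefs={
            **ZERO_EFFECTS,
            "coaching": {"intercept": -1.0, "baseline_hba1c": -0.5},
        },
    )
    members = generate_cohort(cfg)
    spec = cfg.spec_by_name()["baseline_hba1c"]
    for m in members:
        z = (m.covariates["baseline_hba1c"] - spec.params["mu"]) / spec.params["sd"]
        assert math.isclose(m.true_cate["coaching"], -1.0 - 0.5 * z, rel_tol=1e-12)


def test_mean_true_cate_matches_intercept():
    """With tau = -1.0 - 0.5 z, the population mean effect is the intercept."""
    cfg = SimConfig(
        n_members=5000,
        seed=11,
        effect_fn_coefs={
            **ZERO_EFFECTS,
            "coaching": {"intercept": -1.0, "baseline_hba1c": -0.5},
        },
    )
    taus = np.array([m.true_cate["coaching"] for m in generate_cohort(cfg)])
    se = taus.std(ddof=1) / math.sqrt(len(taus))
    assert abs(taus.mean() + 1.0) < 4 * se


def test_confounding_is_real(cohort):
    """Engagement propensity correlates with untreated drift, so the naive
    treated-minus-control contrast is biased away from the true mean effect."""
    prop = np.array([m.truth["engagement_propensity"]["coaching"] for m in cohort])
    drift = np.array([m.truth["drift"] for m in cohort])
    r = np.corrcoef(prop, drift)[0, 1]
    assert abs(r) > 0.1

    big = generate_cohort(SimConfig(n_members=5000, seed=13))
    y = np.array([m.truth["expected_outcome"] for m in big])
    se = y.std(ddof=1) / math.sqrt(len(y))
    for category in CATEGORIES:
        t = np.array([m.truth["received"][category] for m in big])
        naive = y[t == 1].mean() - y[t == 0].mean()
        truth = np.array([m.true_cate[category] for m in big]).mean()
        assert abs(naive - truth) > 3 * se, category


def test_smbg_window_means_encode_effects(cohort):
    """Month-1 readings average to the configured baseline; the month-4 vs
    month-1 contrast carries drift + received effects on the eA1c scale."""
    errs1, errs4 = [], []
    for m in cohort:
        r = np.array(m.smbg_readings)
        m1 = r[(r[:, 0] > 0) & (r[:, 0] <= 30), 1]
        m4 = r[(r[:, 0] > 90) & (r[:, 0] <= 120), 1]
        if len(m1) < 5 or len(m4) < 5:
            continue
        base_bg = ADAG_SLOPE * m.truth["baseline_ea1c"] - 46.7
        expected_delta = ADAG_SLOPE * (m.truth["expected_outcome"] + m.truth["outcome_noise"])
        errs1.append(m1.mean() - base_bg)
        errs4.append(m4.mean() - m1.mean() - expected_delta)
    # Per-member window means are noisy; their population means are not.
    assert abs(np.mean(errs1)) < 1.0   # mg/dL
    assert abs(np.mean(errs4)) < 1.5   # mg/dL


def test_frame_round_trip(cohort):
    members_df, smbg_df, truth_df = cohort_frames(cohort[:25])
    back = members_from_frames(members_df, smbg_df, truth_df)
    for orig, rec in zip(cohort[:25], back):
        assert rec.member_id == orig.member_id
        assert rec.engagement == orig.engagement
        assert rec.smbg_readings == sorted(orig.smbg_readings)
        assert rec.true_cate == pytest.approx(orig.true_cate)
        assert rec.covariates["gender"] == orig.covariates["gender"]
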