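"""Synthetic member cohorts with known ground-truth treatment effects.

Real remote-diabetes-monitoring engagement data is proprietary, so every
downstream stage (outcome computation, cohort assignment, doubly-robust
effect estimation, uplift evaluation, recommendation) is exercised against
cohorts generated here, where the data-generating process is fully known:

* covariates X (demographics, self-reported medical status, preferences),
* confounded engagement: the probability of engaging heavily with each of
  the five action categories is logit-linear in X, and the untreated
  outcome drift shares covariates with those propensities, so naive
  treated-minus-control contrasts are biased by construction;
* per-category true effects tau_c(x), linear in standardized covariates,
  injected into the month-4 glucose level of members whose realized
  engagement crosses the treatment threshold;
* SMBG streams (mg/dL fingerstick readings) whose 30-day window means
  carry the baseline, drift, and injected effects on the estimated-A1c
  scale via the ADAG relation dBG = 28.7 * d(eA1c).

Determinism: each member draws from its own bit-stream keyed by
``(seed, member_index)``, so growing the cohort never reshuffles
previously generated members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np
from scipy import stats

from .config import ADAG_OFFSET, ADAG_SLOPE, CATEGORIES

__all__ = [
    "CovariateSpec",
    "SimConfig",
    "MemberRecord",
    "generate_cohort",
    "true_cate",
    "treatment_probability",
    "default_covariates",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate: how to sample it and how to standardize it.

    kind:
      continuous  -- Normal(mu, sd); params {"mu", "sd"}
      binary      -- Bernoulli(p);   params {"p"}
      categorical -- levels with probabilities; params {"levels", "probs"}
                     and optionally {"codes"} mapping levels to an ordinal
                     numeric scale (used when the covariate enters a linear
                     predictor).
    """

    name: str
    kind: str
    params: dict[str, Any]

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ConfigurationError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "continuous":
            if self.params.get("sd", -1.0) < 0:
                raise ConfigurationError(f"{self.name}: sd must be >= 0")
        elif self.kind == "binary":
            p = self.params.get("p", -1.0)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{self.name}: p must be in [0, 1]")
        else:
            probs = np.asarray(self.params.get("probs", []), dtype=float)
            if len(probs) != len(self.params.get("levels", [])) or not math.isclose(
                probs.sum(), 1.0, abs_tol=1e-9
            ):
                raise ConfigurationError(f"{self.name}: probs must match levels and sum to 1")

    def sample(self, rng: np.random.Generator):
        if self.kind == "continuous":
            return float(rng.normal(self.params["mu"], self.params["sd"]))
        if self.kind == "binary":
            return int(rng.random() < self.params["p"])
        idx = rng.choice(len(self.params["levels"]), p=self.params["probs"])
        return self.params["levels"][idx]

    def standardize(self, value) -> float:
        """Map a sampled value to a z-score under the sampling distribution."""
        if self.kind == "continuous":
            sd = self.params["sd"]
            return (float(value) - self.params["mu"]) / sd if sd > 0 else 0.0
        if self.kind == "binary":
            p = self.params["p"]
            sd = math.sqrt(p * (1.0 - p))
            return (float(value) - p) / sd if sd > 0 else 0.0
        codes = self.params.get("codes")
        if codes is None:
            raise ConfigurationError(
                f"categorical covariate {self.name!r} has no ordinal codes; "
                "it cannot enter a linear predictor"
            )
        xs = np.array([codes[lv] for lv in self.params["levels"]], dtype=float)
        ps = np.asarray(self.params["probs"], dtype=float)
        mu = float(xs @ ps)
        sd = math.sqrt(float(((xs - mu) ** 2) @ ps))
        return (codes[value] - mu) / sd if sd > 0 else 0.0


def default_covariates() -> list[CovariateSpec]:
    """The 12 default covariates: 4 demographic, 6 self-reported, 2 preference."""
    return [
        CovariateSpec("age", "continuous", {"mu": 54.0, "sd": 10.0}),
        CovariateSpec(
            "gender",
            "categorical",
            {"levels": ["female", "male", "other"], "probs": [0.55, 0.43, 0.02]},
        ),
        CovariateSpec("bmi", "continuous", {"mu": 33.0, "sd": 6.0}),
        CovariateSpec(
            "race",
            "categorical",
            {
                "levels": ["white", "black", "hispanic", "asian", "other"],
                "probs": [0.55, 0.18, 0.17, 0.06, 0.04],
            },
        ),
        CovariateSpec("baseline_hba1c", "continuous", {"mu": 8.6, "sd": 1.1}),
        CovariateSpec(
            "self_efficacy",
            "categorical",
            {
                "levels": ["low", "medium", "high"],
                "probs": [0.25, 0.45, 0.30],
                "codes": {"low": 0.0, "medium": 1.0, "high": 2.0},
            },
        ),
        CovariateSpec("insulin_use", "binary", {"p": 0.35}),
        CovariateSpec("oral_meds", "binary", {"p": 0.75}),
        CovariateSpec("flu_vaccine", "binary", {"p": 0.50}),
        CovariateSpec("smoker", "binary", {"p": 0.15}),
        CovariateSpec(
            "comms_pref",
            "categorical",
            {"levels": ["app", "email", "text"], "probs": [0.40, 0.35, 0.25]},
        ),
        CovariateSpec("activity_interest", "continuous", {"mu": 3.0, "sd": 1.0}),
    ]


def _default_propensity_coefs() -> dict[str, dict[str, float]]:
    # Logit-linear latent probability of being a heavy engager per category.
    # Shares baseline_hba1c / self_efficacy / age / activity_interest with
    # the outcome drift, which is what makes engagement confounded.
    return {
        "coaching": {"intercept": 0.0, "self_efficacy": 0.8, "baseline_hba1c": 0.4},
        "monitoring": {
            "intercept": -0.4, "baseline_hba1c": 0.7, "age": 0.3, "self_efficacy": 0.4,
        },
        "physical_activity": {"intercept": -0.5, "activity_interest": 0.9, "bmi": -0.3},
        "nutrition": {"intercept": -0.7, "activity_interest": 0.6, "self_efficacy": 0.4},
        "content": {"intercept": -0.3, "self_efficacy": 0.7, "age": 0.2},
    }


def _default_effect_coefs() -> dict[str, dict[str, float]]:
    # True tau_c(x) in eA1c percentage points (negative = improvement).
    # Mostly negative with a minority positive, and different covariates
    # drive each category so the per-member argmin genuinely varies.
    return {
        "coaching": {"intercept": -0.8, "baseline_hba1c": -0.5, "age": 0.3},
        "monitoring": {"intercept": -0.7, "baseline_hba1c": -0.3, "bmi": -0.35},
        "physical_activity": {"intercept": -0.5, "activity_interest": -0.45, "age": 0.25},
        "nutrition": {"intercept": -0.35, "bmi": -0.35, "self_efficacy": -0.2},
        "content": {"intercept": -0.3, "age": -0.2, "baseline_hba1c": 0.2},
    }


def _default_baseline_outcome_coefs() -> dict[str, float]:
    # Untreated eA1c drift month 4 - month 1. Shares baseline_hba1c,
    # self_efficacy and activity_interest with every category's propensity
    # so that naive treated-vs-control contrasts are confounded for all
    # five categories, not just some.
    return {
        "intercept": -0.2,
        "baseline_hba1c": 0.5,
        "self_efficacy": 0.5,
        "activity_interest": -0.2,
    }


# Engagement count distributions per latent arm (heavy vs light engager).
# Counts are over the 90-day engagement window; nudges are a fixed panel.
_ENGAGEMENT_ARMS: dict[str, dict[str, Any]] = {
    "monitoring": {"kind": "daily_bernoulli", "p_high": 0.86, "p_low": 0.45},
    "coaching": {"kind": "poisson_shift", "high_shift": 3, "high_lam": 2.0, "low_lam": 0.8},
    "physical_activity": {"kind": "binomial_days", "p_high": 0.50, "p_low": 0.12},
    "nutrition": {
        "kind": "nutrition",
        "logs_high_lam": 5.0,
        "logs_low_lam": 0.4,
        "n_nudges": 12,
        "p_yes_high": 0.70,
        "p_yes_low": 0.15,
    },
    "content": {"kind": "nudge_frac", "n_nudges": 12, "p_yes_high": 0.70, "p_yes_low": 0.15},
}


@dataclass
class SimConfig:
    """Full parameterization of a synthetic cohort."""

    n_members: int = 2000
    seed: int = 0
    covariate_spec: list[CovariateSpec] = field(default_factory=default_covariates)
    propensity_coefs: dict[str, dict[str, float]] = field(
        default_factory=_default_propensity_coefs
    )
    effect_fn_coefs: dict[str, dict[str, float]] = field(default_factory=_default_effect_coefs)
    baseline_outcome_coefs: dict[str, float] = field(
        default_factory=_default_baseline_outcome_coefs
    )
    # Baseline month-1 estimated A1c (percent) as a linear predictor.
    baseline_ea1c_coefs: dict[str, float] = field(
        default_factory=lambda: {"intercept": 8.7, "baseline_hba1c": 0.9, "bmi": 0.1}
    )
    noise_sd: float = 0.25  # outcome-level noise, eA1c points
    bg_noise_sd: float = 30.0  # per-reading SMBG noise, mg/dL
    observation_days: int = 120
    read_prob_after_window: float = 0.75  # daily SMBG probability on days 91..120
    type2_rate: float = 0.96
    cgm_rate: float = 0.04
    short_enrollment_rate: float = 0.03
    short_enrollment_days: int = 75

    def __post_init__(self) -> None:
        if self.n_members < 0:
            raise ConfigurationError("n_members must be >= 0")
        if self.noise_sd < 0 or self.bg_noise_sd < 0:
            raise ConfigurationError("noise SDs must be >= 0")
        for table_name in ("propensity_coefs", "effect_fn_coefs"):
            table = getattr(self, table_name)
            missing = set(CATEGORIES) - set(table)
            if missing:
                raise ConfigurationError(f"{table_name} missing categories: {sorted(missing)}")
        # Each spec must validate; duplicate names are configuration errors.
        names = [s.name for s in self.covariate_spec]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate covariate names")

    def spec_by_name(self) -> dict[str, CovariateSpec]:
        return {s.name: s for s in self.covariate_spec}


@dataclass
class MemberRecord:
    """One synthetic member: covariates, engagement, SMBG stream, and truth.

    ``true_cate`` and ``truth`` are the data-generating ground truth; they
    exist only in synthetic cohorts and are never shown to the estimators.
    """

    member_id: str
    covariates: dict[str, Any]
    engagement: dict[str, float]
    smbg_readings: list[tuple[int, float]]
    observation_days: int
    type2_diabetes: bool
    cgm_user: bool
    true_cate: dict[str, float] = field(default_factory=dict)
    truth: dict[str, Any] = field(default_factory=dict)


def _linear_predictor(
    coefs: dict[str, float], covariates: dict[str, Any], specs: dict[str, CovariateSpec]
) -> float:
    total = float(coefs.get("intercept", 0.0))
    for name, coef in coefs.items():
        if name == "intercept":
            continue
        if name not in specs:
            raise ConfigurationError(f"coefficient refers to unknown covariate {name!r}")
        total += coef * specs[name].standardize(covariates[name])
    return total


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _draw_engagement(
    category: str, heavy: bool, window_days: int, rng: np.random.Generator
) -> dict[str, float]:
    arm = _ENGAGEMENT_ARMS[category]
    kind = arm["kind"]
    if kind == "daily_bernoulli":
        # Realized via the SMBG stream itself: return the daily check
        # probability; the caller materializes the per-day pattern.
        return {"_daily_p": arm["p_high"] if heavy else arm["p_low"]}
    if kind == "poisson_shift":
        if heavy:
            return {"coaching_sessions": float(arm["high_shift"] + rng.poisson(arm["high_lam"]))}
        return {"coaching_sessions": float(rng.poisson(arm["low_lam"]))}
    if kind == "binomial_days":
        p = arm["p_high"] if heavy else arm["p_low"]
        return {"active_days": float(rng.binomial(window_days, p))}
    if kind == "nutrition":
        lam = arm["logs_high_lam"] if heavy else arm["logs_low_lam"]
        p_yes = arm["p_yes_high"] if heavy else arm["p_yes_low"]
        n = arm["n_nudges"]
        return {
            "food_logs": float(rng.poisson(lam)),
            "nutrition_nudge_yes_frac": float(rng.binomial(n, p_yes)) / n,
        }
    if kind == "nudge_frac":
        p_yes = arm["p_yes_high"] if heavy else arm["p_yes_low"]
        n = arm["n_nudges"]
        return {"content_nudge_yes_frac": float(rng.binomial(n, p_yes)) / n}
    raise ConfigurationError(f"unknown engagement kind {kind!r}")


# Treatment is defined downstream by thresholding engagement; these mirror
# the default thresholds so the generator can report the exact P(T=1 | x).
_DEFAULT_THRESHOLDS = {
    "monitoring": 70,
    "coaching": 3,
    "physical_activity": 30,
    "nutrition": (2, 0.5),
    "content": 0.5,
}


def _arm_exceed_prob(category: str, heavy: bool, window_days: int) -> float:
    """P(engagement >= default threshold) within one latent arm, in closed form."""
    arm = _ENGAGEMENT_ARMS[category]
    thr = _DEFAULT_THRESHOLDS[category]
    if category == "monitoring":
        p = arm["p_high"] if heavy else arm["p_low"]
        return float(stats.binom.sf(thr - 1, window_days, p))
    if category == "coaching":
        if heavy:
            return 1.0  # shifted by the threshold itself
        return float(stats.poisson.sf(thr - 1, arm["low_lam"]))
    if category == "physical_activity":
        p = arm["p_high"] if heavy else arm["p_low"]
        return float(stats.binom.sf(thr - 1, window_days, p))
    if category == "nutrition":
        lam = arm["logs_high_lam"] if heavy else arm["logs_low_lam"]
        p_yes = arm["p_yes_high"] if heavy else arm["p_yes_low"]
        logs_thr, frac_thr = thr
        n = arm["n_nudges"]
        p_logs = float(stats.poisson.sf(logs_thr - 1, lam))
        p_frac = float(stats.binom.sf(math.ceil(frac_thr * n) - 1, n, p_yes))
        return 1.0 - (1.0 - p_logs) * (1.0 - p_frac)
    if category == "content":
        p_yes = arm["p_yes_high"] if heavy else arm["p_yes_low"]
        n = arm["n_nudges"]
        return float(stats.binom.sf(math.ceil(thr * n) - 1, n, p_yes))
    raise KeyError(category)


def treatment_probability(member: MemberRecord, category: str, window_days: int = 90) -> float:
    """Exact P(T=1 | x) for the default thresholds, from the generating model.

    This is the true propensity of the thresholded treatment indicator: a
    mixture over the latent heavy/light engagement arm. Useful as the
    oracle propensity in double-robustness checks.
    """
    if category not in CATEGORIES:
        raise KeyError(f"unknown action category {category!r}")
    pi = member.truth["engagement_propensity"][category]
    p_hi = _arm_exceed_prob(category, True, window_days)
    p_lo = _arm_exceed_prob(category, False, window_days)
    return pi * p_hi + (1.0 - pi) * p_lo


def true_cate(member: MemberRecord, category: str) -> float:
    """The stored data-generating effect of ``category`` for this member."""
    if category not in CATEGORIES:
        raise KeyError(f"unknown action category {category!r}")
    return member.true_cate[category]


def _generate_member(
    idx: int, config: SimConfig, specs: dict[str, CovariateSpec], window_days: int
) -> MemberRecord:
    rng = np.random.default_rng([config.seed, idx])

    covariates: dict[str, Any] = {}
    for spec in config.covariate_spec:
        covariates[spec.name] = spec.sample(rng)
    # Engagement-summary covariates outside the five action categories.
    covariates["app_use_days"] = int(rng.binomial(90, 0.35))
    covariates["web_gap_days"] = float(rng.exponential(12.0))

    type2 = bool(rng.random() < config.type2_rate)
    cgm = bool(rng.random() < config.cgm_rate)
    short = bool(rng.random() < config.short_enrollment_rate)
    obs_days = config.short_enrollment_days if short else config.observation_days

    # Latent heavy-engager indicator per category (the confounded part).
    propensity = {
        c: _sigmoid(_linear_predictor(config.propensity_coefs[c], covariates, specs))
        for c in CATEGORIES
    }
    heavy = {c: bool(rng.random() < propensity[c]) for c in CATEGORIES}

    engagement: dict[str, float] = {}
    daily_check_p = 0.6
    for c in CATEGORIES:
        drawn = _draw_engagement(c, heavy[c], window_days, rng)
        if "_daily_p" in drawn:
            daily_check_p = drawn.pop("_daily_p")
        engagement.update(drawn)

    # True effects and outcome pieces, all on the eA1c (percent) scale.
    tau = {
        c: _linear_predictor(config.effect_fn_coefs[c], covariates, specs) for c in CATEGORIES
    }
    drift = _linear_predictor(config.baseline_outcome_coefs, covariates, specs)
    ea1c_base = _linear_predictor(config.baseline_ea1c_coefs, covariates, specs)
    noise = float(rng.normal(0.0, config.noise_sd)) if config.noise_sd > 0 else 0.0

    # SMBG check days: days 1..window drive the monitoring metric; later
    # days use a fixed program-average check rate.
    n_days = obs_days
    day_idx = np.arange(1, n_days + 1)
    p_read = np.where(day_idx <= window_days, daily_check_p, config.read_prob_after_window)
    is_read_day = rng.random(n_days) < p_read
    engagement["smbg_check_days"] = float(
        np.count_nonzero(is_read_day[: min(window_days, n_days)])
    )

    # Received treatment = thresholded engagement (matches assign_cohorts).
    received = {
        "monitoring": engagement["smbg_check_days"] >= _DEFAULT_THRESHOLDS["monitoring"],
        "coaching": engagement["coaching_sessions"] >= _DEFAULT_THRESHOLDS["coaching"],
        "physical_activity": engagement["active_days"]
        >= _DEFAULT_THRESHOLDS["physical_activity"],
        "nutrition": (
            engagement["food_logs"] >= _DEFAULT_THRESHOLDS["nutrition"][0]
            or engagement["nutrition_nudge_yes_frac"] >= _DEFAULT_THRESHOLDS["nutrition"][1]
        ),
        "content": engagement["content_nudge_yes_frac"] >= _DEFAULT_THRESHOLDS["content"],
    }
    total_effect = sum(tau[c] for c in CATEGORIES if received[c])

    # Month-window mean BG: month 1 carries the baseline; the untreated
    # drift ramps linearly across months; treatment effects and the
    # outcome-level noise are realized in the month-4 window only, so the
    # interim months 2-3 (which re-enter the model as covariates) carry
    # drift but never mediate the injected effect.
    bg_month1 = ADAG_SLOPE * ea1c_base - ADAG_OFFSET
    month_of_day = np.minimum((day_idx - 1) // 30, 3)
    month_frac = month_of_day / 3.0
    day_mean = (
        bg_month1
        + month_frac * ADAG_SLOPE * drift
        + (month_of_day == 3) * ADAG_SLOPE * (total_effect + noise)
    )

    values = day_mean + rng.normal(0.0, config.bg_noise_sd, size=n_days)
    readings = [
        (int(d), float(v)) for d, v, keep in zip(day_idx, values, is_read_day) if keep
    ]

    return MemberRecord(
        member_id=f"M{idx:06d}",
        covariates=covariates,
        engagement=engagement,
        smbg_readings=readings,
        observation_days=obs_days,
        type2_diabetes=type2,
        cgm_user=cgm,
        true_cate=tau,
        truth={
            "engagement_propensity": propensity,
            "heavy_engager": heavy,
            "received": received,
            "drift": drift,
            "baseline_ea1c": ea1c_base,
            "outcome_noise": noise,
            "expected_outcome": drift + total_effect,
        },
    )


def generate_cohort(config: SimConfig, window_days: int = 90) -> list[MemberRecord]:
    """Generate ``config.n_members`` members, deterministically in the seed."""
    specs = config.spec_by_name()
    return [_generate_member(i, config, specs, window_days) for i in range(config.n_members)]


# ---------------------------------------------------------------------------
# Tabular export (CSV dialect shared with the rest of the pipeline)


def cohort_frames(members: Sequence[MemberRecord]):
    """Members as three tidy DataFrames: wide member table, SMBG, truth."""
    import pandas as pd

    rows = []
    for m in members:
        row: dict[str, Any] = {"member_id": m.member_id}
        row.update(m.covariates)
        row.update(m.engagement)
        row["observation_days"] = m.observation_days
        row["type2_diabetes"] = int(m.type2_diabetes)
        row["cgm_user"] = int(m.cgm_user)
        rows.append(row)
    members_df = pd.DataFrame(rows)

    smbg_df = pd.DataFrame(
        [
            {"member_id": m.member_id, "day": d, "value_mgdl": v}
            for m in members
            for d, v in m.smbg_readings
        ],
        columns=["member_id", "day", "value_mgdl"],
    )
    truth_df = pd.DataFrame(
        [
            {"member_id": m.member_id, "category": c, "true_cate": m.true_cate[c]}
            for m in members
            for c in CATEGORIES
        ],
        columns=["member_id", "category", "true_cate"],
    )
    return members_df, smbg_df, truth_df


def members_from_frames(members_df, smbg_df, truth_df=None) -> list[MemberRecord]:
    """Inverse of :func:`cohort_frames` (truth is optional on the way in)."""
    engagement_cols = {
        "smbg_check_days",
        "coaching_sessions",
        "active_days",
        "food_logs",
        "nutrition_nudge_yes_frac",
        "content_nudge_yes_frac",
    }
    meta_cols = {"member_id", "observation_days", "type2_diabetes", "cgm_user"}
    readings_by_member: dict[str, list[tuple[int, float]]] = {}
    for mid, day, value in smbg_df[["member_id", "day", "value_mgdl"]].itertuples(index=False):
        readings_by_member.setdefault(mid, []).append((int(day), float(value)))

    truth_by_member: dict[str, dict[str, float]] = {}
    if truth_df is not None:
        for mid, cat, tc in truth_df[["member_id", "category", "true_cate"]].itertuples(
            index=False
        ):
            truth_by_member.setdefault(mid, {})[cat] = float(tc)

    members = []
    for row in members_df.to_dict(orient="records"):
        mid = row["member_id"]
        members.append(
            MemberRecord(
                member_id=mid,
                covariates={
                    k: v for k, v in row.items() if k not in engagement_cols | meta_cols
                },
                engagement={k: float(row[k]) for k in engagement_cols if k in row},
                smbg_readings=sorted(readings_by_member.get(mid, [])),
                observation_days=int(row.get("observation_days", 120)),
                type2_diabetes=bool(row.get("type2_diabetes", 1)),
                cgm_user=bool(row.get("cgm_user", 0)),
                true_cate=truth_by_member.get(mid, {}),
            )
        )
    return members


def write_cohort(members: Iterable[MemberRecord], out_dir) -> None:
    """Write members.csv, smbg.csv and truth.csv under ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    members_df, smbg_df, truth_df = cohort_frames(list(members))
    members_df.to_csv(out / "members.csv", index=False)
    smbg_df.to_csv(out / "smbg.csv", index=False)
    truth_df.to_csv(out / "truth.csv", index=False)


def read_cohort(in_dir) -> list[MemberRecord]:
    """Read a cohort written by :func:`write_cohort`."""
    from pathlib import Path

    import pandas as pd

    path = Path(in_dir)
    members_df = pd.read_csv(path / "members.csv")
    smbg_df = pd.read_csv(path / "smbg.csv")
    truth_path = path / "truth.csv"
    truth_df = pd.read_csv(truth_path) if truth_path.exists() else None
    return members_from_frames(members_df, smbg_df, truth_df)
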