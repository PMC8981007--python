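"""Doubly-robust estimation of heterogeneous treatment effects (CATE).

For each action category the observed sample is (X, T, Y): covariates, a
binary treatment flag from the engagement threshold, and the change in
estimated A1c. The conditional average treatment effect

    tau(x) = E[g(1, X) - g(0, X) | X = x]

is learned with the DR-learner recipe: fit an outcome regression g(T, X)
and a propensity model f(X) = P(T=1 | X), form the debiased pseudo-outcome

    psi = (g1 - g0) + T (Y - g1) / p - (1 - T) (Y - g0) / (1 - p),

and regress psi on X with a random forest. psi is unbiased for tau(x)
whenever EITHER nuisance model is correct, which is what makes the final
regression robust to misspecification of one of them.

Nuisances are cross-fitted (K-fold, stratified on T) so no row's
pseudo-outcome uses a nuisance model trained on itself. Propensities are
clipped into [0.01, 0.99] to bound the inverse weights. The data is split
65:35 into train/validation; validation MSE against the validation fold's
own cross-fitted pseudo-outcomes is the model-selection signal used by
the threshold sweep.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    HistGradientBoostingClassifier,
    HistGradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.model_selection import StratifiedKFold, train_test_split

from .config import CATEGORIES, default_config
from .outcomes import OutcomeRecord
from .synthetic import MemberRecord

__all__ = [
    "CateEstimate",
    "FitReport",
    "DRLearnerModel",
    "build_feature_matrix",
    "dr_pseudo_outcome",
    "fit_dr_learner",
    "predict_cate",
    "estimate_ate",
]

_CFG = default_config()["model"]

_CATEGORICAL_FEATURES = ("gender", "race", "comms_pref", "self_efficacy")
_NUMERIC_FEATURES = (
    "age",
    "bmi",
    "baseline_hba1c",
    "insulin_use",
    "oral_meds",
    "flu_vaccine",
    "smoker",
    "activity_interest",
    "app_use_days",
    "web_gap_days",
)
_HYPO_MGDL = 70.0
_HYPER_MGDL = 180.0


class FitError(RuntimeError):
    """The DR learner could not be fitted (degenerate cohorts or data)."""


@dataclass
class CateEstimate:
    member_id: str
    category: str
    tau_hat: float


@dataclass
class FitReport:
    category: str
    n_train: int
    n_validation: int
    validation_mse: float
    split_ratio: float
    seed: int


@dataclass
class DRLearnerModel:
    """A fitted CATE model plus everything needed to reproduce psi."""

    cate_model: RandomForestRegressor
    feature_names: list[str]
    clip_bounds: tuple[float, float]
    train_index: np.ndarray
    validation_index: np.ndarray
    psi_train: np.ndarray
    psi_validation: np.ndarray
    tau_train: np.ndarray
    tau_validation: np.ndarray

    def predict(self, X) -> np.ndarray:
        X = _check_columns(X, self.feature_names)
        return self.cate_model.predict(X)


def _check_columns(X, feature_names: list[str]) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if list(X.columns) != list(feature_names):
            missing = set(feature_names) - set(X.columns)
            extra = set(X.columns) - set(feature_names)
            raise ValueError(
                f"feature columns do not match training columns "
                f"(missing={sorted(missing)}, unexpected={sorted(extra)})"
            )
        return X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(feature_names):
        raise ValueError(
            f"expected {len(feature_names)} feature columns, got {X.shape[1]}"
        )
    return X


def _day_rate(readings, window, predicate) -> float:
    """Fraction of SMBG-check days in the window satisfying ``predicate``.

    Rates rather than raw day counts: a raw count scales with how often a
    member checks at all, i.e. with the monitoring exposure itself, which
    would leak the treatment into the covariates.
    """
    lo, hi = window
    check_days = {d for d, v in readings if lo < d <= hi}
    if not check_days:
        return 0.0
    hit_days = {d for d, v in readings if lo < d <= hi and predicate(v)}
    return len(hit_days) / len(check_days)


def build_feature_matrix(
    members: Sequence[MemberRecord], outcomes: Sequence[OutcomeRecord] | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Numeric model matrix for the eligible cohort.

    Covers demographics, self-reported medical status, preferences, app/web
    usage summaries, interim eA1c (months 2-3), and hypo-/hyperglycemia day
    counts in months 1-3. Categoricals are one-hot encoded with all levels
    kept; the column order is fixed by construction and returned alongside.
    Missing interim eA1c values (insufficient readings) are imputed with the
    column mean.
    """
    rows = []
    outcomes = list(outcomes) if outcomes is not None else [None] * len(members)
    for m, o in zip(members, outcomes):
        row: dict[str, float] = {}
        for name in _NUMERIC_FEATURES:
            row[name] = float(m.covariates[name])
        for name in _CATEGORICAL_FEATURES:
            row[name] = m.covariates[name]
        if o is not None:
            row["ea1c_month2"] = o.ea1c_month2
            row["ea1c_month3"] = o.ea1c_month3
        for k in (1, 2, 3):
            window = (30 * (k - 1), 30 * k)
            row[f"hypo_day_rate_month{k}"] = _day_rate(
                m.smbg_readings, window, lambda v: v < _HYPO_MGDL
            )
            row[f"hyper_day_rate_month{k}"] = _day_rate(
                m.smbg_readings, window, lambda v: v > _HYPER_MGDL
            )
        rows.append(row)

    df = pd.DataFrame(rows)
    df = pd.get_dummies(df, columns=list(_CATEGORICAL_FEATURES), dtype=float)
    all_missing = [c for c in df.columns if df[c].isna().all()]
    if all_missing:
        raise ValueError(f"feature columns with no observed values: {all_missing}")
    df = df.fillna(df.mean(numeric_only=True))
    df.index = pd.Index([m.member_id for m in members], name="member_id")
    return df, list(df.columns)


def dr_pseudo_outcome(y, t, g1, g0, p, clip_bounds: tuple[float, float] | None = None):
    """The doubly-robust pseudo-outcome psi (vectorized).

    psi = (g1 - g0) + t (y - g1)/p - (1 - t)(y - g0)/(1 - p). When
    ``clip_bounds`` is given, p is clipped into it first; p outside (0, 1)
    after clipping is an error rather than an inf.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    g1 = np.asarray(g1, dtype=float)
    g0 = np.asarray(g0, dtype=float)
    p = np.asarray(p, dtype=float)
    if clip_bounds is not None:
        lo, hi = clip_bounds
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError(f"invalid clip bounds {clip_bounds}")
        p = np.clip(p, lo, hi)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("propensities must lie strictly inside (0, 1)")
    return (g1 - g0) + t * (y - g1) / p - (1.0 - t) * (y - g0) / (1.0 - p)


def _crossfit_nuisances(
    X: np.ndarray,
    T: np.ndarray,
    Y: np.ndarray,
    n_folds: int,
    seed: int,
    clip_bounds: tuple[float, float],
    outcome_params: dict,
    propensity_params: dict,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Out-of-fold (g1, g0, p) predictions via stratified K-fold cross-fitting."""
    n = len(Y)
    if T.sum() == 0 or T.sum() == n:
        raise FitError("both treatment and control rows are required")
    n_folds = min(n_folds, int(T.sum()), int(n - T.sum()))
    if n_folds < 2:
        raise FitError("too few rows in one cohort for cross-fitting")
    g1 = np.empty(n)
    g0 = np.empty(n)
    p = np.empty(n)
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for fit_idx, hold_idx in splitter.split(X, T):
        XT_fit = np.column_stack([T[fit_idx], X[fit_idx]])
        outcome = HistGradientBoostingRegressor(random_state=seed, **outcome_params)
        outcome.fit(XT_fit, Y[fit_idx])
        X_hold = X[hold_idx]
        g1[hold_idx] = outcome.predict(np.column_stack([np.ones(len(hold_idx)), X_hold]))
        g0[hold_idx] = outcome.predict(np.column_stack([np.zeros(len(hold_idx)), X_hold]))
        propensity = HistGradientBoostingClassifier(random_state=seed, **propensity_params)
        propensity.fit(X[fit_idx], T[fit_idx])
        p[hold_idx] = propensity.predict_proba(X_hold)[:, 1]
    return g1, g0, np.clip(p, clip_bounds[0], clip_bounds[1])


def fit_dr_learner(
    X,
    T,
    Y,
    split_ratio: float | None = None,
    seed: int = 0,
    n_folds: int | None = None,
    clip_bounds: tuple[float, float] | None = None,
    category: str = "",
    model_config: dict | None = None,
    split: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[DRLearnerModel, FitReport]:
    """Fit the DR learner for one category.

    1. split rows ``split_ratio``:(1-ratio) into train/validation,
       stratified on T; 2. cross-fit nuisances on the training rows and
       form psi; 3. fit a random forest of psi on X (the CATE model);
       4. cross-fit nuisances on the validation rows and score
       MSE(tau_hat, psi_validation).

    ``split`` overrides step 1 with precomputed (train, validation) row
    indices — used when several categories must share one validation set.
    """
    cfg = dict(_CFG)
    if model_config:
        cfg.update(model_config)
    split_ratio = float(cfg["split_ratio"] if split_ratio is None else split_ratio)
    n_folds = int(cfg["n_folds"] if n_folds is None else n_folds)
    clip = tuple(cfg["clip_bounds"]) if clip_bounds is None else clip_bounds

    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(np.asarray(X).shape[1])
    ]
    Xa = _check_columns(X, feature_names)
    T = np.asarray(T, dtype=int)
    Y = np.asarray(Y, dtype=float)
    if len({int(v) for v in np.unique(T)} - {0, 1}) > 0:
        raise ValueError("T must be binary 0/1")
    if T.sum() < 2 or (len(T) - T.sum()) < 2:
        raise FitError("training data must contain both cohorts")

    if split is None:
        idx = np.arange(len(Y))
        train_idx, val_idx = train_test_split(
            idx, train_size=split_ratio, random_state=seed, stratify=T
        )
    else:
        train_idx, val_idx = split
    train_idx = np.sort(np.asarray(train_idx))
    val_idx = np.sort(np.asarray(val_idx))
    if T[train_idx].sum() < 2 or (len(train_idx) - T[train_idx].sum()) < 2:
        raise FitError("training split must contain both cohorts")

    g1_tr, g0_tr, p_tr = _crossfit_nuisances(
        Xa[train_idx], T[train_idx], Y[train_idx], n_folds, seed, clip,
        dict(cfg["outcome_learner"]), dict(cfg["propensity_learner"]),
    )
    psi_tr = dr_pseudo_outcome(Y[train_idx], T[train_idx], g1_tr, g0_tr, p_tr)
    bad = np.flatnonzero(~np.isfinite(psi_tr))
    if len(bad):
        raise FitError(f"non-finite pseudo-outcomes at training rows {bad[:10].tolist()}")

    forest = RandomForestRegressor(random_state=seed, n_jobs=1, **cfg["cate_learner"])
    forest.fit(Xa[train_idx], psi_tr)

    g1_v, g0_v, p_v = _crossfit_nuisances(
        Xa[val_idx], T[val_idx], Y[val_idx], n_folds, seed, clip,
        dict(cfg["outcome_learner"]), dict(cfg["propensity_learner"]),
    )
    psi_v = dr_pseudo_outcome(Y[val_idx], T[val_idx], g1_v, g0_v, p_v)
    tau_tr = forest.predict(Xa[train_idx])
    tau_v = forest.predict(Xa[val_idx])
    mse = float(np.mean((tau_v - psi_v) ** 2))

    model = DRLearnerModel(
        cate_model=forest,
        feature_names=feature_names,
        clip_bounds=clip,
        train_index=train_idx,
        validation_index=val_idx,
        psi_train=psi_tr,
        psi_validation=psi_v,
        tau_train=tau_tr,
        tau_validation=tau_v,
    )
    report = FitReport(
        category=category,
        n_train=len(train_idx),
        n_validation=len(val_idx),
        validation_mse=mse,
        split_ratio=split_ratio,
        seed=seed,
    )
    return model, report


def predict_cate(
    model: DRLearnerModel, X, member_ids: Sequence[str] | None = None, category: str = ""
) -> list[CateEstimate]:
    """Per-member tau_hat for new rows; deterministic given the fitted model."""
    tau = model.predict(X)
    if not np.all(np.isfinite(tau)):
        raise ValueError("non-finite CATE predictions")
    if member_ids is None:
        if isinstance(X, pd.DataFrame):
            member_ids = [str(i) for i in X.index]
        else:
            member_ids = [str(i) for i in range(len(tau))]
    return [
        CateEstimate(member_id=mid, category=category, tau_hat=float(t))
        for mid, t in zip(member_ids, tau)
    ]


def estimate_ate(
    X, T, Y, seed: int = 0, n_folds: int | None = None,
    clip_bounds: tuple[float, float] | None = None, model_config: dict | None = None,
) -> tuple[float, float]:
    """Cross-fitted DR estimate of the average treatment effect and its SE.

    Returns (mean(psi), sd(psi)/sqrt(n)) over the full sample — the plain
    AIPW point estimate used for null-calibration and robustness checks.
    """
    cfg = dict(_CFG)
    if model_config:
        cfg.update(model_config)
    n_folds = int(cfg["n_folds"] if n_folds is None else n_folds)
    clip = tuple(cfg["clip_bounds"]) if clip_bounds is None else clip_bounds
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    T = np.asarray(T, dtype=int)
    Y = np.asarray(Y, dtype=float)
    g1, g0, p = _crossfit_nuisances(
        Xa, T, Y, n_folds, seed, clip,
        dict(cfg["outcome_learner"]), dict(cfg["propensity_learner"]),
    )
    psi = dr_pseudo_outcome(Y, T, g1, g0, p)
    return float(psi.mean()), float(psi.std(ddof=1) / np.sqrt(len(psi)))
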