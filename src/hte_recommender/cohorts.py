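"""Treatment/control cohort assignment from engagement thresholds.

Each action category turns a continuous engagement metric into a binary
exposure: a member whose 90-day engagement meets the category threshold
(inclusive) is in that category's treatment cohort, otherwise control.
A member can be treated in several categories at once; one below every
threshold belongs to the residual "other" group.

The threshold itself is a modelling choice: raising it shrinks the
treatment cohort (more imbalance, noisier fits) while concentrating on
heavier engagers (larger apparent effect). ``threshold_sweep`` +
``select_threshold`` operationalize that trade-off: fit the doubly-robust
learner at each candidate threshold, then among candidates whose
validation MSE lies within a relative band of the minimum, pick the most
negative average predicted effect (ties to the smaller threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import CATEGORIES, default_config
from .synthetic import MemberRecord

__all__ = [
    "ThresholdSpec",
    "CohortAssignment",
    "SweepRecord",
    "engagement_metrics",
    "default_thresholds",
    "assign_cohorts",
    "threshold_sweep",
    "select_threshold",
]

_CFG = default_config()


@dataclass(frozen=True)
class ThresholdSpec:
    """Treatment rule for one category: OR over (metric, min) clauses."""

    category: str
    clauses: tuple[tuple[str, float], ...]

    def is_treated(self, metrics: dict[str, float]) -> bool:
        return any(metrics[m] >= t for m, t in self.clauses)


@dataclass
class CohortAssignment:
    member_id: str
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def other(self) -> bool:
        """True when the member is below every category threshold."""
        return not any(self.flags.values())


@dataclass
class SweepRecord:
    category: str
    metric: str
    threshold: float
    n_treatment: int
    n_control: int
    model_mse: float = float("nan")
    avg_treatment_effect: float = float("nan")
    degenerate: bool = False


def engagement_metrics(member: MemberRecord) -> dict[str, float]:
    """Per-category engagement metrics over the first 90 days."""
    e = member.engagement
    return {
        "smbg_check_days": float(e["smbg_check_days"]),
        "coaching_sessions": float(e["coaching_sessions"]),
        "active_days": float(e["active_days"]),
        "food_logs": float(e["food_logs"]),
        "nutrition_nudge_yes_frac": float(e["nutrition_nudge_yes_frac"]),
        "content_nudge_yes_frac": float(e["content_nudge_yes_frac"]),
    }


def default_thresholds() -> dict[str, ThresholdSpec]:
    """The configured default thresholds, one spec per category."""
    out = {}
    for category, clauses in _CFG["thresholds"].items():
        out[category] = ThresholdSpec(
            category,
            tuple((c["metric"], float(c["min"])) for c in clauses),
        )
    return out


def assign_cohorts(
    members: Sequence[MemberRecord], thresholds: dict[str, ThresholdSpec] | None = None
) -> list[CohortAssignment]:
    """Binary treatment flags for all five categories, per member."""
    if thresholds is None:
        thresholds = default_thresholds()
    missing = set(CATEGORIES) - set(thresholds)
    if missing:
        raise ValueError(f"missing ThresholdSpec for categories: {sorted(missing)}")
    assignments = []
    for m in members:
        metrics = engagement_metrics(m)
        assignments.append(
            CohortAssignment(
                member_id=m.member_id,
                flags={c: thresholds[c].is_treated(metrics) for c in CATEGORIES},
            )
        )
    return assignments


def treatment_vector(
    assignments: Sequence[CohortAssignment], category: str
) -> np.ndarray:
    return np.array([int(a.flags[category]) for a in assignments], dtype=int)


def threshold_sweep(
    members: Sequence[MemberRecord],
    outcomes,
    category: str,
    grid: Sequence[float],
    split_seed: int = 0,
    min_cohort_size: int | None = None,
    model_config: dict | None = None,
) -> list[SweepRecord]:
    """Fit the DR learner at each candidate threshold for one category.

    The swept clause is the category's first (count-based) clause; any
    additional clause (nutrition's nudge fraction) is held at its default.
    Grid values whose treatment or control cohort falls below
    ``min_cohort_size`` are flagged degenerate and not fitted.
    """
    from .hte import build_feature_matrix, fit_dr_learner

    if len(grid) == 0:
        raise ValueError("grid must be nonempty")
    if list(grid) != sorted(grid):
        raise ValueError("grid must be sorted ascending")
    if min_cohort_size is None:
        min_cohort_size = int(_CFG["sweep"]["min_cohort_size"])

    base = default_thresholds()
    metric = base[category].clauses[0][0]
    X, _ = build_feature_matrix(members, outcomes)
    Y = np.array([o.outcome_y for o in outcomes], dtype=float)

    records = []
    for thr in grid:
        clauses = ((metric, float(thr)),) + base[category].clauses[1:]
        specs = dict(base)
        specs[category] = ThresholdSpec(category, clauses)
        assignments = assign_cohorts(members, specs)
        T = treatment_vector(assignments, category)
        n_t, n_c = int(T.sum()), int(len(T) - T.sum())
        rec = SweepRecord(category, metric, float(thr), n_t, n_c)
        if min(n_t, n_c) < min_cohort_size:
            rec.degenerate = True
        else:
            model, report = fit_dr_learner(
                X, T, Y, seed=split_seed, model_config=model_config
            )
            rec.model_mse = report.validation_mse
            rec.avg_treatment_effect = float(np.mean(model.tau_validation))
        records.append(rec)
    return records


def select_threshold(
    sweep: Sequence[SweepRecord], mse_band: float | None = None
) -> ThresholdSpec:
    """Pick the sweep record with the most negative effect among those whose
    MSE is within ``mse_band`` (relative) of the minimum; ties -> smaller
    threshold. Raises if every record is degenerate."""
    if mse_band is None:
        mse_band = float(_CFG["sweep"]["mse_band"])
    fitted = [r for r in sweep if not r.degenerate and np.isfinite(r.model_mse)]
    if not fitted:
        raise ValueError("threshold selection impossible: all sweep records degenerate")
    mse_min = min(r.model_mse for r in fitted)
    in_band = [r for r in fitted if r.model_mse <= mse_min * (1.0 + mse_band)]
    best = min(in_band, key=lambda r: (r.avg_treatment_effect, r.threshold))
    return ThresholdSpec(best.category, ((best.metric, best.threshold),))


def assignments_frame(assignments: Sequence[CohortAssignment]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "member_id": a.member_id,
                **{c: int(a.flags[c]) for c in CATEGORIES},
                "other": int(a.other),
            }
            for a in assignments
        ]
    )
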