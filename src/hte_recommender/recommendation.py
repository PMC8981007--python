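"""Per-member action recommendations from per-category CATE predictions.

The recommended action is the category with the most negative predicted
treatment effect (largest predicted drop in estimated A1c). Members whose
predictions are non-negative everywhere get "none": there is no action
the model expects to help them. Ties break by the fixed category order
(coaching, monitoring, physical_activity, nutrition, content).

``matched_outcome_analysis`` quantifies the value of personalization on
held-out members: within each category's treatment cohort, members whose
received action coincides with their recommendation ("matched") are
compared with those engaged in a non-recommended action.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohorts import CohortAssignment
from .config import CATEGORIES
from .outcomes import OutcomeRecord

__all__ = [
    "Recommendation",
    "recommend",
    "matched_outcome_analysis",
    "recommendation_distribution",
    "personalization_effect",
]


@dataclass
class Recommendation:
    member_id: str
    recommended_category: str  # one of the five, or "none"
    tau_by_category: dict[str, float]
    matched: bool | None = None


def recommend(tau_by_category: Mapping[str, float], member_id: str = "") -> Recommendation:
    """Argmin-tau recommendation; "none" unless some predicted effect is < 0."""
    missing = set(CATEGORIES) - set(tau_by_category)
    if missing:
        raise KeyError(f"tau_by_category missing categories: {sorted(missing)}")
    best = min(CATEGORIES, key=lambda c: (tau_by_category[c], CATEGORIES.index(c)))
    category = best if tau_by_category[best] < 0 else "none"
    return Recommendation(
        member_id=member_id,
        recommended_category=category,
        tau_by_category={c: float(tau_by_category[c]) for c in CATEGORIES},
    )


def mark_matched(
    recommendations: Sequence[Recommendation],
    assignments: Mapping[str, CohortAssignment],
) -> None:
    """Set each recommendation's ``matched`` flag from cohort membership."""
    for rec in recommendations:
        if rec.recommended_category == "none":
            rec.matched = False
        else:
            a = assignments[rec.member_id]
            rec.matched = bool(a.flags[rec.recommended_category])


def matched_outcome_analysis(
    recommendations: Sequence[Recommendation],
    assignments: Mapping[str, CohortAssignment],
    outcomes: Mapping[str, OutcomeRecord],
) -> pd.DataFrame:
    """Mean outcome Y for matched vs unmatched members, per category + pooled.

    For each category, among members in its treatment cohort: "matched"
    means that category is also the member's recommendation. An empty
    partition yields NaN means (undefined, not an error). The pooled row
    averages over category memberships, so a member treated in several
    categories contributes once per membership.
    """
    mark_matched(recommendations, assignments)
    rows = []
    pooled_matched: list[float] = []
    pooled_unmatched: list[float] = []
    for category in CATEGORIES:
        y_matched, y_unmatched = [], []
        for rec in recommendations:
            a = assignments[rec.member_id]
            if not a.flags[category]:
                continue
            y = outcomes[rec.member_id].outcome_y
            if math.isnan(y):
                continue
            if rec.recommended_category == category:
                y_matched.append(y)
            else:
                y_unmatched.append(y)
        pooled_matched.extend(y_matched)
        pooled_unmatched.extend(y_unmatched)
        rows.append(_partition_row(category, y_matched, y_unmatched))
    rows.append(_partition_row("pooled", pooled_matched, pooled_unmatched))
    return pd.DataFrame(rows)


def _partition_row(label: str, matched: list[float], unmatched: list[float]) -> dict:
    mean_m = float(np.mean(matched)) if matched else math.nan
    mean_u = float(np.mean(unmatched)) if unmatched else math.nan
    return {
        "category": label,
        "n_matched": len(matched),
        "n_unmatched": len(unmatched),
        "mean_y_matched": mean_m,
        "mean_y_unmatched": mean_u,
        "difference": mean_m - mean_u,
    }


def recommendation_distribution(
    recommendations: Sequence[Recommendation],
) -> dict[str, float]:
    """Fraction of each category among members with a (non-"none") recommendation."""
    recommended = [r for r in recommendations if r.recommended_category != "none"]
    if not recommended:
        return {}
    n = len(recommended)
    return {
        c: sum(r.recommended_category == c for r in recommended) / n for c in CATEGORIES
    }


def personalization_effect(
    cate_by_member: Mapping[str, Mapping[str, float]],
    assignments: Mapping[str, CohortAssignment],
) -> pd.DataFrame:
    """Mean predicted effect as-received vs if-optimal, per category.

    For members in each category's treatment cohort: "as-received" is the
    mean predicted effect of that category; "if-optimal" is the mean of the
    per-member minimum over all categories. By construction if-optimal <=
    as-received.
    """
    rows = []
    for category in CATEGORIES:
        received, optimal = [], []
        for mid, a in assignments.items():
            if not a.flags[category] or mid not in cate_by_member:
                continue
            taus = cate_by_member[mid]
            received.append(float(taus[category]))
            optimal.append(min(float(taus[c]) for c in CATEGORIES))
        rows.append(
            {
                "category": category,
                "n": len(received),
                "mean_tau_as_received": float(np.mean(received)) if received else math.nan,
                "mean_tau_if_optimal": float(np.mean(optimal)) if optimal else math.nan,
            }
        )
    return pd.DataFrame(rows)
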