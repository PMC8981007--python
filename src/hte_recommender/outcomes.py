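"""Estimated A1c from SMBG streams, the outcome Y, and eligibility filtering.

Estimated A1c (eA1c, percent) is derived from self-monitored blood glucose
through the ADAG relation ``eA1c = (mean BG over past 30 days + 46.7) / 28.7``.
The intervention outcome is ``Y = eA1c(month 4) - eA1c(month 1)``; a more
negative Y is a better clinical outcome.

Month-k windows are the half-open day ranges ``(30(k-1), 30k]`` with day 0
the enrollment day. Readings outside [50, 400] mg/dL are dropped before
averaging, and a window with fewer than 5 valid readings is treated as
insufficient data (an explicit signal, never a silent default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .config import default_config
from .synthetic import MemberRecord

__all__ = [
    "InsufficientDataError",
    "OutcomeRecord",
    "estimated_a1c",
    "compute_outcome",
    "apply_eligibility",
    "FUNNEL_RULES",
]

_CFG = default_config()
_ADAG_SLOPE = float(_CFG["adag"]["slope_mgdl_per_pct"])
_ADAG_OFFSET = float(_CFG["adag"]["offset_mgdl"])
_VALID_LO, _VALID_HI = (float(v) for v in _CFG["smbg"]["valid_range_mgdl"])
_MIN_READINGS = int(_CFG["smbg"]["min_readings_per_window"])
_WINDOW_DAYS = int(_CFG["smbg"]["window_days"])
_MIN_ENROLLMENT_DAYS = int(_CFG["eligibility"]["min_enrollment_days"])
_BASELINE_MIN = float(_CFG["eligibility"]["baseline_ea1c_min_pct"])


class InsufficientDataError(ValueError):
    """A 30-day window had fewer than the required number of valid readings."""

    def __init__(self, n_valid: int, window: tuple[int, int]):
        self.n_valid = n_valid
        self.window = window
        super().__init__(
            f"window ({window[0]}, {window[1]}] has {n_valid} valid readings; "
            f"{_MIN_READINGS} required"
        )


@dataclass
class OutcomeRecord:
    member_id: str
    ea1c_month1: float = math.nan
    ea1c_month2: float = math.nan
    ea1c_month3: float = math.nan
    ea1c_month4: float = math.nan
    outcome_y: float = math.nan
    eligible: bool = False
    exclusion_reason: str = ""
    n_valid: dict[int, int] = field(default_factory=dict)

    def ea1c(self, month: int) -> float:
        return getattr(self, f"ea1c_month{month}")


def _valid_in_window(
    readings: Iterable[tuple[int, float]], window: tuple[int, int]
) -> np.ndarray:
    lo, hi = window
    vals = [
        v for d, v in readings if lo < d <= hi and _VALID_LO <= v <= _VALID_HI
    ]
    return np.asarray(vals, dtype=float)


def estimated_a1c(
    readings: Sequence[tuple[int, float]], window: tuple[int, int]
) -> float:
    """eA1c (percent) over a 30-day half-open window ``(lo, hi]``.

    Raises :class:`InsufficientDataError` when fewer than 5 valid (50-400
    mg/dL) readings fall inside the window.
    """
    lo, hi = window
    if hi - lo != _WINDOW_DAYS:
        raise ValueError(f"window must span {_WINDOW_DAYS} days, got {window}")
    vals = _valid_in_window(readings, window)
    if len(vals) < _MIN_READINGS:
        raise InsufficientDataError(len(vals), window)
    return (float(vals.mean()) + _ADAG_OFFSET) / _ADAG_SLOPE


def mean_bg_for_ea1c(ea1c: float) -> float:
    """Inverse ADAG map: the 30-day mean BG (mg/dL) that yields ``ea1c``."""
    return _ADAG_SLOPE * ea1c - _ADAG_OFFSET


def compute_outcome(member: MemberRecord) -> OutcomeRecord:
    """Month 1-4 eA1c and the outcome Y for one member.

    Months with insufficient valid readings are left NaN; the record then
    fails eligibility downstream rather than raising here. Months 2-3 are
    computed as well because they re-enter the model as covariates.
    """
    rec = OutcomeRecord(member_id=member.member_id)
    for k in (1, 2, 3, 4):
        window = (_WINDOW_DAYS * (k - 1), _WINDOW_DAYS * k)
        vals = _valid_in_window(member.smbg_readings, window)
        rec.n_valid[k] = len(vals)
        if len(vals) >= _MIN_READINGS:
            setattr(rec, f"ea1c_month{k}", (float(vals.mean()) + _ADAG_OFFSET) / _ADAG_SLOPE)
    if not (math.isnan(rec.ea1c_month1) or math.isnan(rec.ea1c_month4)):
        rec.outcome_y = rec.ea1c_month4 - rec.ea1c_month1
    return rec


#: Eligibility rules in fixed funnel order; each excluded member is counted
#: once, at its first failing rule.
FUNNEL_RULES: tuple[str, ...] = (
    "enrollment_lt_4_months",
    "not_type2",
    "cgm_user",
    "insufficient_smbg",
    "baseline_below_7.5",
)


def _first_failing_rule(member: MemberRecord, outcome: OutcomeRecord) -> str:
    if member.observation_days < _MIN_ENROLLMENT_DAYS:
        return "enrollment_lt_4_months"
    if not member.type2_diabetes:
        return "not_type2"
    if member.cgm_user:
        return "cgm_user"
    if outcome.n_valid.get(1, 0) < _MIN_READINGS or outcome.n_valid.get(4, 0) < _MIN_READINGS:
        return "insufficient_smbg"
    if math.isnan(outcome.ea1c_month1) or outcome.ea1c_month1 < _BASELINE_MIN:
        return "baseline_below_7.5"
    return ""


def apply_eligibility(
    members: Sequence[MemberRecord], outcomes: Sequence[OutcomeRecord]
) -> tuple[list[MemberRecord], dict[str, int]]:
    """Filter to the study population; return (retained, funnel counts).

    Retains members enrolled at least 4 months, with self-reported type 2
    diabetes, no self-reported CGM use, at least 5 valid SMBG readings in
    both month one and month four, and month-1 eA1c >= 7.5%. Mutates each
    OutcomeRecord's ``eligible`` / ``exclusion_reason`` in place and
    preserves input order.
    """
    if len(members) != len(outcomes):
        raise ValueError("members and outcomes must align one-to-one")
    funnel = {rule: 0 for rule in FUNNEL_RULES}
    retained = []
    for member, outcome in zip(members, outcomes):
        reason = _first_failing_rule(member, outcome)
        outcome.exclusion_reason = reason
        outcome.eligible = reason == ""
        if reason:
            funnel[reason] += 1
        else:
            retained.append(member)
    return retained, funnel


def outcomes_from_frame(df) -> list[OutcomeRecord]:
    """Rebuild outcome records from a frame written by :func:`outcomes_frame`."""
    records = []
    for row in df.to_dict(orient="records"):
        records.append(
            OutcomeRecord(
                member_id=row["member_id"],
                ea1c_month1=float(row["ea1c_month1"]),
                ea1c_month2=float(row["ea1c_month2"]),
                ea1c_month3=float(row["ea1c_month3"]),
                ea1c_month4=float(row["ea1c_month4"]),
                outcome_y=float(row["outcome_y"]),
                eligible=bool(row["eligible"]),
                exclusion_reason=(
                    "" if not isinstance(row["exclusion_reason"], str)
                    else row["exclusion_reason"]
                ),
                n_valid={1: int(row["n_valid_month1"]), 4: int(row["n_valid_month4"])},
            )
        )
    return records


def outcomes_frame(outcomes: Sequence[OutcomeRecord]):
    """Outcome records as a tidy DataFrame (one row per member)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "member_id": o.member_id,
                "ea1c_month1": o.ea1c_month1,
                "ea1c_month2": o.ea1c_month2,
                "ea1c_month3": o.ea1c_month3,
                "ea1c_month4": o.ea1c_month4,
                "outcome_y": o.outcome_y,
                "n_valid_month1": o.n_valid.get(1, 0),
                "n_valid_month4": o.n_valid.get(4, 0),
                "eligible": int(o.eligible),
                "exclusion_reason": o.exclusion_reason,
            }
            for o in outcomes
        ]
    )
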