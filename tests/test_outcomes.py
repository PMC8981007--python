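"""eA1c computation, outcome Y, and the eligibility funnel."""

import math
from pathlib import Path

import pandas as pd
import pytest

from hte_recommender.outcomes import (
    FUNNEL_RULES,
    InsufficientDataError,
    apply_eligibility,
    compute_outcome,
    estimated_a1c,
    mean_bg_for_ea1c,
)
from hte_recommender.synthetic import MemberRecord, members_from_frames

DATA = Path(__file__).parent / "data"


def _readings(values, start_day=1):
    return [(start_day + i, v) for i, v in enumerate(values)]


def _member(mid="m", reads=(), obs=120, t2d=True, cgm=False):
    return MemberRecord(
        member_id=mid, covariates={}, engagement={}, smbg_readings=list(reads),
        observation_days=obs, type2_diabetes=t2d, cgm_user=cgm,
    )


class TestEstimatedA1c:
    def test_hand_values(self):
        # mean BG 240.3 -> (240.3 + 46.7) / 28.7 = 10.0
        assert estimated_a1c(_readings([240.3] * 6), (0, 30)) == pytest.approx(10.0)
        # 28.7 * 7 - 46.7 = 154.2 -> 7.0
        assert estimated_a1c(_readings([154.2] * 6), (0, 30)) == pytest.approx(7.0)

    @pytest.mark.parametrize("k", range(6, 13))
    def test_adag_exact_inverse(self, k):
        bg = mean_bg_for_ea1c(float(k))
        assert estimated_a1c(_readings([bg] * 5), (0, 30)) == pytest.approx(k, abs=1e-12)

    def test_too_few_valid_readings(self):
        with pytest.raises(InsufficientDataError):
            estimated_a1c(_readings([200.0] * 4), (0, 30))

    def test_out_of_range_readings_dropped(self):
        reads = _readings([200.0] * 5) + [(10, 30.0), (11, 480.0)]
        assert estimated_a1c(reads, (0, 30)) == pytest.approx((200.0 + 46.7) / 28.7)
        # ...and a window kept alive only by invalid readings is insufficient
        with pytest.raises(InsufficientDataError):
            estimated_a1c(_readings([45.0] * 10), (0, 30))

    def test_window_is_half_open(self):
        reads = [(0, 100.0)] + _readings([200.0] * 5, start_day=26)
        # day 0 is outside (0, 30]; day 30 is inside
        assert estimated_a1c(reads, (0, 30)) == pytest.approx((200.0 + 46.7) / 28.7)

    def test_wrong_window_span_rejected(self):
        with pytest.raises(ValueError):
            estimated_a1c(_readings([200.0] * 6), (0, 31))


class TestComputeOutcome:
    def test_outcome_is_month4_minus_month1(self):
        reads = [(d, mean_bg_for_ea1c(9.0)) for d in range(1, 31)] + [
            (d, mean_bg_for_ea1c(7.5)) for d in range(91, 121)
        ]
        rec = compute_outcome(_member(reads=reads))
        assert rec.outcome_y == pytest.approx(7.5 - 9.0)

    def test_identical_windows_give_zero(self):
        reads = [(d, 180.0) for d in range(1, 121)]
        assert compute_outcome(_member(reads=reads)).outcome_y == pytest.approx(0.0)

    def test_insufficient_window_propagates_as_nan_not_error(self):
        reads = [(d, 180.0) for d in range(1, 31)]  # month 1 only
        rec = compute_outcome(_member(reads=reads))
        assert math.isnan(rec.ea1c_month4) and math.isnan(rec.outcome_y)


class TestEligibility:
    def _funnel(self, members):
        outcomes = [compute_outcome(m) for m in members]
        return apply_eligibility(members, outcomes)

    def test_all_pass(self):
        reads = [(d, 250.0) for d in range(1, 121)]
        members = [_member(mid=f"m{i}", reads=reads) for i in range(10)]
        retained, funnel = self._funnel(members)
        assert len(retained) == 10
        assert all(v == 0 for v in funnel.values())

    def test_each_rule_and_first_fail_attribution(self):
        good = [(d, 250.0) for d in range(1, 121)]
        low = [(d, 150.0) for d in range(1, 121)]  # eA1c 6.86 < 7.5
        members = [
            _member("short", reads=good, obs=100),
            _member("t1d", reads=good, t2d=False),
            # fails both CGM and baseline rules: counted at cgm_user only
            _member("cgm_low", reads=low, cgm=True),
            _member("sparse", reads=good[:4]),
            _member("low", reads=low),
            _member("ok", reads=good),
        ]
        retained, funnel = self._funnel(members)
        assert [m.member_id for m in retained] == ["ok"]
        assert funnel == {
            "enrollment_lt_4_months": 1,
            "not_type2": 1,
            "cgm_user": 1,
            "insufficient_smbg": 1,
            "baseline_below_7.5": 1,
        }

    def test_funnel_counts_sum_and_order_stability(self, cohort):
        outcomes = [compute_outcome(m) for m in cohort]
        retained, funnel = apply_eligibility(cohort, outcomes)
        assert len(cohort) - len(retained) == sum(funnel.values())
        assert list(funnel) == list(FUNNEL_RULES)
        ids = [m.member_id for m in cohort]
        assert [m.member_id for m in retained] == [
            i for i in ids if i in {m.member_id for m in retained}
        ]

    def test_committed_fixture_reproduces_exact_counts(self):
        """Frozen 50-member fixture: per-rule exclusions are bit-stable."""
        members = members_from_frames(
            pd.read_csv(DATA / "funnel_members.csv"),
            pd.read_csv(DATA / "funnel_smbg.csv"),
        )
        retained, funnel = self._funnel(members)
        assert len(members) == 50
        assert len(retained) == 25
        assert funnel == {
            "enrollment_lt_4_months": 5,
            "not_type2": 4,
            "cgm_user": 3,
            "insufficient_smbg": 6,
            "baseline_below_7.5": 7,
        }
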