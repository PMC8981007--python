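"""Build the committed 50-member eligibility-funnel fixture.

Run once from the repository root:

    python scripts/make_funnel_fixture.py

Writes tests/data/funnel_members.csv / funnel_smbg.csv. The fixture is
constructed rule by rule, so the expected funnel counts are known by
design: 5 short-enrollment, 4 not type 2, 3 CGM users, 6 with too few
month-1 readings, 7 with baseline eA1c below 7.5%, and 25 eligible.
"""

from pathlib import Path

from hte_recommender.config import CATEGORIES
from hte_recommender.synthetic import MemberRecord, cohort_frames

HIGH_BG = 250.0  # eA1c (250 + 46.7) / 28.7 = 10.34 -> passes the 7.5 floor
LOW_BG = 150.0   # eA1c 6.85 -> fails the 7.5 floor


def readings(months=(1, 2, 3, 4), per_month=8, value=HIGH_BG):
    out = []
    for k in months:
        lo = 30 * (k - 1)
        for i in range(per_month):
            out.append((lo + 2 + 3 * i, value))
    return out


def member(i, *, obs=120, t2d=True, cgm=False, reads=None):
    return MemberRecord(
        member_id=f"F{i:03d}",
        covariates={
            "age": 50.0 + i % 20, "gender": "female" if i % 2 else "male",
            "bmi": 30.0, "race": "white", "baseline_hba1c": 8.5,
            "self_efficacy": "medium", "insulin_use": i % 2, "oral_meds": 1,
            "flu_vaccine": 0, "smoker": 0, "comms_pref": "app",
            "activity_interest": 3.0, "app_use_days": 20, "web_gap_days": 10.0,
        },
        engagement={
            "smbg_check_days": 40.0, "coaching_sessions": 1.0, "active_days": 10.0,
            "food_logs": 1.0, "nutrition_nudge_yes_frac": 0.2,
            "content_nudge_yes_frac": 0.3,
        },
        smbg_readings=reads if reads is not None else readings(),
        observation_days=obs,
        type2_diabetes=t2d,
        cgm_user=cgm,
        true_cate={c: 0.0 for c in CATEGORIES},
    )


def build():
    members, i = [], 0
    for _ in range(25):  # eligible
        members.append(member(i)); i += 1
    for _ in range(5):   # enrolled < 4 months
        members.append(member(i, obs=75, reads=readings(months=(1, 2)))); i += 1
    for _ in range(4):   # no type-2 self-report
        members.append(member(i, t2d=False)); i += 1
    for _ in range(3):   # CGM user
        members.append(member(i, cgm=True)); i += 1
    for _ in range(6):   # only 4 valid month-1 readings
        r = readings(months=(2, 3, 4)) + readings(months=(1,), per_month=4)
        members.append(member(i, reads=sorted(r))); i += 1
    for _ in range(7):   # baseline eA1c below 7.5
        members.append(member(i, reads=readings(value=LOW_BG))); i += 1
    return members


def main():
    out = Path(__file__).resolve().parent.parent / "tests" / "data"
    out.mkdir(parents=True, exist_ok=True)
    members_df, smbg_df, _ = cohort_frames(build())
    members_df.to_csv(out / "funnel_members.csv", index=False)
    smbg_df.to_csv(out / "funnel_smbg.csv", index=False)
    print(f"wrote {len(members_df)} members, {len(smbg_df)} readings to {out}")


if __name__ == "__main__":
    main()
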