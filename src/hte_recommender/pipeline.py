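"""End-to-end orchestration: simulate -> outcomes -> cohorts -> DR fits
(five categories) -> uplift evaluation -> recommendations -> report.

All five category models share one 65:35 train/validation split of the
eligible cohort so that evaluation and the matched-vs-unmatched analysis
use a common validation set. Every stochastic stage derives its stream
from the single run seed, so a run is byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import cohorts as cohorts_mod
from . import evaluation as eval_mod
from . import hte, outcomes as outcomes_mod, recommendation as rec_mod
from .config import CATEGORIES, default_config
from .synthetic import MemberRecord, SimConfig, generate_cohort, write_cohort

log = logging.getLogger("hte_recommender")

__all__ = ["sim_config_from_dict", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


_SIM_SCALAR_KEYS = (
    "n_members",
    "seed",
    "noise_sd",
    "bg_noise_sd",
    "observation_days",
    "read_prob_after_window",
    "type2_rate",
    "cgm_rate",
    "short_enrollment_rate",
    "short_enrollment_days",
)


def sim_config_from_dict(d: dict[str, Any] | None) -> SimConfig:
    """SimConfig from the ``sim`` config section (scalar knobs only; the
    covariate/coefficient defaults are the generator's)."""
    d = d or {}
    kwargs = {k: d[k] for k in _SIM_SCALAR_KEYS if k in d}
    return SimConfig(**kwargs)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def run_pipeline(config: dict | None = None, out_dir=None, seed: int | None = None) -> dict:
    """Run every stage; write artifacts under ``out_dir``; return the report."""
    config = config or default_config()
    if seed is not None:
        config = dict(config)
        config["sim"] = {**config.get("sim", {}), "seed": int(seed)}
    run_seed = int(config["sim"].get("seed", 0))
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    report: dict[str, Any] = {"seed": run_seed}

    # --- simulate -----------------------------------------------------
    stage = "simulate"
    try:
        sim_cfg = sim_config_from_dict(config.get("sim"))
        members = generate_cohort(sim_cfg)
        if out is not None:
            write_cohort(members, out)
        log.info("stage=%s members_out=%d", stage, len(members))
    except Exception as exc:  # noqa: BLE001 - uniform stage wrapping
        raise PipelineError(stage, exc) from exc

    # --- outcomes + eligibility --------------------------------------
    stage = "outcomes"
    try:
        outcome_records = [outcomes_mod.compute_outcome(m) for m in members]
        retained, funnel = outcomes_mod.apply_eligibility(members, outcome_records)
        outcomes_by_id = {o.member_id: o for o in outcome_records}
        if out is not None:
            outcomes_mod.outcomes_frame(outcome_records).to_csv(
                out / "outcomes.csv", index=False
            )
            pd.DataFrame(
                [{"rule": r, "n_excluded": n} for r, n in funnel.items()]
            ).to_csv(out / "funnel.csv", index=False)
        report["funnel"] = funnel
        report["n_members"] = len(members)
        report["n_eligible"] = len(retained)
        log.info("stage=%s members_in=%d retained=%d", stage, len(members), len(retained))
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- cohort assignment -------------------------------------------
    stage = "cohorts"
    try:
        thresholds = cohorts_mod.default_thresholds()
        assignments = cohorts_mod.assign_cohorts(retained, thresholds)
        assignments_by_id = {a.member_id: a for a in assignments}
        min_size = int(config["sweep"]["min_cohort_size"])
        for c in CATEGORIES:
            T = cohorts_mod.treatment_vector(assignments, c)
            if min(int(T.sum()), int(len(T) - T.sum())) < min_size:
                raise ValueError(
                    f"category {c!r}: treatment/control cohort below minimum "
                    f"size {min_size} (n_t={int(T.sum())}, n={len(T)})"
                )
        report["thresholds"] = {
            c: [list(cl) for cl in thresholds[c].clauses] for c in CATEGORIES
        }
        report["treatment_fraction"] = {
            c: float(cohorts_mod.treatment_vector(assignments, c).mean())
            for c in CATEGORIES
        }
        if out is not None:
            cohorts_mod.assignments_frame(assignments).to_csv(
                out / "cohorts.csv", index=False
            )
        log.info("stage=%s members_in=%d", stage, len(assignments))
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- DR fits (shared validation split) ---------------------------
    stage = "fit_hte"
    try:
        eligible_outcomes = [outcomes_by_id[m.member_id] for m in retained]
        X, feature_names = hte.build_feature_matrix(retained, eligible_outcomes)
        Y = np.array([o.outcome_y for o in eligible_outcomes])
        split_ratio = float(config["model"]["split_ratio"])
        train_idx, val_idx = train_test_split(
            np.arange(len(Y)), train_size=split_ratio, random_state=run_seed
        )
        # fit_dr_learner works with sorted indices; keep ours identical so
        # tau_validation rows align with val_idx everywhere below.
        train_idx, val_idx = np.sort(train_idx), np.sort(val_idx)
        models: dict[str, hte.DRLearnerModel] = {}
        reports: dict[str, hte.FitReport] = {}
        for c in CATEGORIES:
            T = cohorts_mod.treatment_vector(assignments, c)
            models[c], reports[c] = hte.fit_dr_learner(
                X, T, Y,
                seed=run_seed,
                category=c,
                model_config=config.get("model"),
                split=(train_idx, val_idx),
            )
            log.info(
                "stage=%s category=%s n_train=%d n_val=%d mse=%.4f",
                stage, c, reports[c].n_train, reports[c].n_validation,
                reports[c].validation_mse,
            )
        report["fit"] = {
            c: {
                "n_train": reports[c].n_train,
                "n_validation": reports[c].n_validation,
                "validation_mse": reports[c].validation_mse,
            }
            for c in CATEGORIES
        }
        if out is not None:
            for c in CATEGORIES:
                ids = X.index.to_numpy()
                frame = pd.DataFrame(
                    {
                        "member_id": np.concatenate(
                            [ids[train_idx], ids[val_idx]]
                        ),
                        "tau_hat": np.concatenate(
                            [models[c].tau_train, models[c].tau_validation]
                        ),
                        "split": ["train"] * len(train_idx)
                        + ["validation"] * len(val_idx),
                    }
                )
                frame.to_csv(out / f"cate_{c}.csv", index=False)
            _write_json(report["fit"], out / "fit_report.json")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- uplift evaluation on the common validation set --------------
    stage = "evaluate"
    try:
        n_q = int(config["evaluation"]["n_quantiles"])
        n_perm = int(config["evaluation"]["n_permutations"])
        Y_val = Y[val_idx]
        eval_report = {}
        for i, c in enumerate(CATEGORIES):
            T_val = cohorts_mod.treatment_vector(assignments, c)[val_idx]
            scores = -models[c].tau_validation  # most negative tau first
            curve = eval_mod.cumulative_gain_curve(scores, T_val, Y_val, n_q)
            rand_mean, rand_sd, _ = eval_mod.random_auuc_baseline(
                T_val, Y_val, n_q, n_perm, seed=run_seed + i
            )
            eval_report[c] = {
                "auuc_model": curve.auuc,
                "auuc_random_mean": rand_mean,
                "auuc_random_sd": rand_sd,
                "total_gain": curve.total_gain,
                "n_undefined_quantiles": len(curve.undefined_fractions),
            }
            if out is not None:
                pd.DataFrame(
                    {"fraction": curve.fractions, "gain": curve.gains}
                ).to_csv(out / f"uplift_{c}.csv", index=False)
            log.info(
                "stage=%s category=%s auuc=%.3f random=%.3f",
                stage, c, curve.auuc, rand_mean,
            )
        report["evaluation"] = eval_report
        if out is not None:
            _write_json(eval_report, out / "eval_report.json")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- recommendations (validation members) ------------------------
    stage = "recommend"
    try:
        val_ids = X.index.to_numpy()[val_idx]
        recommendations = []
        cate_by_member: dict[str, dict[str, float]] = {}
        for row, mid in enumerate(val_ids):
            taus = {c: float(models[c].tau_validation[row]) for c in CATEGORIES}
            cate_by_member[mid] = taus
            recommendations.append(rec_mod.recommend(taus, member_id=mid))
        val_assignments = {mid: assignments_by_id[mid] for mid in val_ids}
        matched = rec_mod.matched_outcome_analysis(
            recommendations, val_assignments, outcomes_by_id
        )
        distribution = rec_mod.recommendation_distribution(recommendations)
        personalization = rec_mod.personalization_effect(cate_by_member, val_assignments)
        report["recommendation_distribution"] = distribution
        report["matched_analysis"] = matched.to_dict(orient="records")
        report["personalization"] = personalization.to_dict(orient="records")
        if out is not None:
            pd.DataFrame(
                [
                    {
                        "member_id": r.member_id,
                        "recommended_category": r.recommended_category,
                        "matched": int(bool(r.matched)),
                        **{f"tau_{c}": r.tau_by_category[c] for c in CATEGORIES},
                    }
                    for r in recommendations
                ]
            ).to_csv(out / "recommendations.csv", index=False)
            matched.to_csv(out / "matched_analysis.csv", index=False)
            _write_json(distribution, out / "distribution.json")
        log.info("stage=%s recommendations=%d", stage, len(recommendations))
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    if out is not None:
        _write_json(report, out / "report.json")
    return report
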