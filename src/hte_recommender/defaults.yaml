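# Default run configuration. All program-level constants live here so a run
# is fully described by (this file + overrides + seed).

adag:
  # eA1c (%) = (mean BG over past 30 days [mg/dL] + offset) / slope
  slope_mgdl_per_pct: 28.7
  offset_mgdl: 46.7

smbg:
  valid_range_mgdl: [50.0, 400.0]
  min_readings_per_window: 5
  window_days: 30

eligibility:
  min_enrollment_days: 120
  baseline_ea1c_min_pct: 7.5

engagement_window_days: 90

# Engagement thresholds for treatment-cohort membership within the first
# 90 days. A member meeting ANY clause of a category is treated (>=).
thresholds:
  coaching:
    - {metric: coaching_sessions, min: 3}
  monitoring:
    - {metric: smbg_check_days, min: 70}
  physical_activity:
    - {metric: active_days, min: 30}
  nutrition:
    - {metric: food_logs, min: 2}
    - {metric: nutrition_nudge_yes_frac, min: 0.5}
  content:
    - {metric: content_nudge_yes_frac, min: 0.5}

model:
  split_ratio: 0.65          # train fraction; remainder is validation
  n_folds: 5                 # cross-fitting folds for nuisance models
  clip_bounds: [0.01, 0.99]  # propensity clipping
  outcome_form: s            # single regressor with T as a feature
  outcome_learner: {max_iter: 150, max_depth: 3, learning_rate: 0.1}
  propensity_learner: {max_iter: 150, max_depth: 3, learning_rate: 0.1}
  cate_learner: {n_estimators: 200, min_samples_leaf: 20}

sweep:
  min_cohort_size: 50   # smaller treatment or control cohort -> degenerate
  mse_band: 0.10        # relative band above min MSE for threshold selection

evaluation:
  n_quantiles: 10
  n_permutations: 200

sim:
  n_members: 2000
  seed: 0
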