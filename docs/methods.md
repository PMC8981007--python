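# Methods

This note documents the modelling choices behind `hte_recommender`: what
the synthetic cohort generator emulates, how the doubly-robust learner
is configured, what the uplift evaluation measures, and the numerical
conventions adopted where the underlying study design leaves choices
open.

## Outcome: estimated A1c from SMBG

Estimated A1c is computed from self-monitored blood glucose with the
ADAG relation `eA1c = (mean BG + 46.7) / 28.7` (BG in mg/dL, eA1c in
percent). Month-k windows are the half-open day ranges `(30(k−1), 30k]`
with day 0 the enrollment day; "month 1" is therefore the trailing
window ending at day 30. Readings outside 50–400 mg/dL are dropped
before averaging, and a window with fewer than 5 valid readings raises
an explicit insufficient-data signal rather than returning a default.
eA1c is an approximation to laboratory HbA1c and is treated here as a
population-level outcome; no per-member calibration is attempted.

Eligibility is applied as a fixed-order funnel (enrollment ≥ 120 days,
type-2 self-report, no CGM, ≥5 valid readings in months one *and* four,
month-1 eA1c ≥ 7.5 %); each excluded member is counted once, at its
first failing rule, which makes funnel counts sum exactly to the number
excluded.

## Synthetic cohort generator

The generator is the package's substitute for proprietary member data.
It produces, per member: 12 covariates (4 demographic, 6 self-reported,
2 preference) plus app/web usage summaries; latent "heavy engager"
indicators per category with logit-linear propensities in standardized
covariates; engagement counts drawn from arm-specific binomial/Poisson
distributions; and an SMBG stream whose 30-day window means encode the
outcome. Key design decisions:

* **Effects live on the eA1c scale.** True effects τ_c(x) are linear in
  standardized covariates and converted to glucose offsets via
  ΔBG = 28.7 × ΔeA1c, so ground truth is stated in the outcome's units
  and the injected effect equals E[Y(1) − Y(0)] exactly.
* **Treatment is the thresholded engagement, not the latent arm.** A
  member's received effect is injected if and only if realized
  engagement crosses the same threshold the analysis pipeline applies,
  so generator truth and cohort assignment can never disagree. The
  exact propensity P(T=1 | x) of this thresholded indicator is available
  in closed form (`treatment_probability`) as a mixture over the latent
  arm, which the double-robustness checks use as the oracle propensity.
* **Effects are realized in the month-4 window.** The untreated drift
  ramps linearly across months, but treatment effects (and the
  outcome-level noise, SD 0.25 eA1c points) enter only the month-4
  glucose level. Interim eA1c (months 2–3) therefore carries
  confounder information but never mediates the effect — necessary
  because interim eA1c re-enters the model as a covariate, and a
  covariate downstream of treatment would absorb the very effect being
  estimated.
* **Confounding is deliberate and acts in every category.** The
  untreated drift shares covariates (baseline HbA1c, self-efficacy,
  activity interest) with all five engagement propensities, with
  coefficients chosen so the naive treated-minus-control contrast is
  biased away from the true mean effect by many standard errors in
  every category — including after accounting for the partial
  cancellation between drift confounding and effect-modifier selection
  that otherwise arises when the same covariate drives both.
* **Determinism.** Each member draws from a bit-stream keyed by
  (seed, member index); growing the cohort never reshuffles existing
  members, and identical configurations are bitwise reproducible.

What the generator does **not** emulate: dropout/attrition, nudge
delivery timing, serial correlation in glucose beyond monthly means,
measurement-device error structure, or dependence between action
categories beyond shared covariates. Passing tests therefore certify
the estimator pipeline, not the realism of any particular effect size;
the real-data magnitudes reported for RDMPs are not reproducible from
synthetic data and are not targeted.

Default scale choices: cohorts of 2 000 members for routine runs and
5 000 where statistical acceptance checks need power; per-reading noise
30 mg/dL; ~75 % daily reading probability outside the engagement
window. These give month-window eA1c standard errors of ≈0.2 points,
comparable to the injected effect heterogeneity (SD ≈ 0.5 points).

## Cohort assignment and threshold selection

Thresholds are inclusive (≥), matching their stated form; nutrition is
an OR of its two clauses (≥2 food logs, or ≥50 % yes-responses). The
sweep fits the DR learner at each candidate threshold and records
validation MSE, mean predicted effect and cohort sizes; candidates
whose smaller cohort falls below 50 members are flagged degenerate and
not fitted. Selection takes, among candidates within a 10 % relative
band of the minimum MSE, the most negative mean effect, breaking ties
toward the smaller threshold. The band rule is one concrete reading of
"minimize modelling error while optimizing treatment effect"; both the
band and the minimum cohort size are configurable.

## DR learner configuration

* **Nuisance roles.** The outcome model g(T,X) is a gradient-boosted
  *regressor* (T appended to X as a feature, evaluated at T=1/0 for the
  counterfactual pair); the propensity f(X) is a gradient-boosted
  *classifier*. This is the statistically coherent assignment for a
  continuous outcome and a binary treatment.
* **Cross-fitting.** Nuisances are fitted in K=5 stratified folds so no
  row's pseudo-outcome uses a model trained on that row; without this,
  own-observation overfitting biases ψ toward the observed residuals.
* **Clipping.** Propensities are clipped to [0.01, 0.99] to bound the
  inverse weights. Severe overlap violations are prevented upstream by
  excluding treatment-determining quantities from the covariates: in
  particular hypo-/hyperglycemia exposure enters as a *rate per
  SMBG-check day*, not a raw day count, because raw counts scale with
  checking frequency — the monitoring exposure itself.
* **Final stage and validation.** A random-forest regression of ψ on X
  is the CATE model. Validation MSE is measured against the validation
  fold's own cross-fitted ψ (true τ being unobservable); this is the
  quantity the threshold sweep minimizes. The 65:35 split is shared
  across all five categories in the pipeline so that evaluation and the
  matched analysis use a common validation set.
* **Degenerate inputs.** Single-cohort data, non-finite ψ, or feature
  mismatches raise typed errors; all-constant features collapse τ̂ to
  the DR ATE, as expected.

## Uplift evaluation

Members are ranked by predicted benefit (score = −τ̂, descending,
stable ties). Uplift at fraction q is the treated-minus-control mean of
−Y within the top q; cumulative gain is uplift × q × n with (0, 0)
prepended. AUUC is the trapezoidal area under the gain curve divided by
the total gain — the normalization under which a random ranking has
expectation 0.5 exactly and the straight-line curve scores 0.5 by
identity (the unnormalized area is also reported). Quantile bins
containing a single cohort are recorded as undefined and linearly
interpolated across when integrating. AUUC is invariant to strictly
monotone transformations of the scores; a zero total gain makes the
normalized value undefined and is reported as an error rather than NaN.

## Recommendation policy

The recommendation is argmin-τ̂ over the five categories, issued only
when the minimum is negative; exact ties break by the fixed order
coaching, monitoring, physical activity, nutrition, content. Propensity
to engage is deliberately not part of the ranking — the policy answers
"which action would help most", not "which action is the member likely
to take"; an engagement-weighted policy would be a separate layer. The
matched-vs-unmatched analysis is restricted to validation-split members
inside at least one treatment cohort; empty partitions report NaN means
rather than failing. Pooled means weight by category membership, so a
member treated in several categories contributes once per membership
(both per-category and pooled views are reported since no canonical
pooling weight exists).

## Numerical conventions and limitations

* All five category models are refitted from a single run seed; runs
  are byte-reproducible given (config, seed).
* No confidence intervals are attached to per-member τ̂; only the
  DR-ATE helper reports a standard error. Honest causal-forest
  machinery, instrumental variables and sensitivity analysis are out of
  scope.
* Categories are modelled independently; interactions between
  simultaneously received interventions are additive by construction in
  the generator and unmodelled in the estimator.
* The eligibility filter conditions on month-1 outcomes, so estimates
  describe the filtered population, not all enrollees.
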