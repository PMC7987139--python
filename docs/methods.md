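# Methods

## The model

`screenrisk` estimates individualized breast-cancer risk for women in a
biennial mammography screening program from four routinely collected
predictors: age, first-degree family history of breast cancer, previous
benign breast disease (BBD; Dupont–Page grouping plus "prior biopsy,
unknown diagnosis"), and previous mammographic features (mass,
calcifications, asymmetry, architectural distortion, or multiple findings).
Both invasive cancer and DCIS count as events.

Because the predictors are updated at every screen, a standard Cox model
with baseline covariates would discard most of the information. We use a
*partly conditional* Cox formulation: each screening visit at time `s`
(the landmark) contributes one record carrying the covariates measured at
`s`, frozen, together with the residual time `T − s` to the event or to
censoring. The hazard of the residual time `t` given the landmark profile
`Z(s)` is modelled as

    λ(t | Z(s)) = λ0(t) · exp(β′ Z(s)),

a proportional-hazards model on the *residual-time* axis, pooling all
landmarks. One woman contributes as many records as she has visits;
records are treated as working-independent in the partial likelihood and
the within-woman dependence is absorbed by a Huber sandwich covariance
clustered on the woman (the standard estimating-equation construction for
partly conditional models). A woman with an event contributes person-time
from her first mammogram to diagnosis; event-free women are censored two
years after their last attended mammogram, the program's follow-up rule.

Absolute risk over a horizon τ from a landmark at which the woman is
cancer-free is

    risk(τ | Z) = 1 − exp(−Λ0(τ) · exp(β′ Z)),

with Λ0 the Breslow step-function estimate of the cumulative baseline
hazard on the residual-time axis. The exponential form (rather than the
product-limit form) differs by < 1e−4 at screening-program event rates and
composes directly with the step function.

## Estimation

* Newton–Raphson with step-halving, at most 50 iterations, convergence at
  gradient 2-norm < 1e−8; risk-set statistics are accumulated by suffix
  sums so one iteration is O(np + events·p²).
* **Ties.** Efron's approximation by default (stacked registry data tie
  heavily); Breslow available via `ties="breslow"`. Exact algebraic
  identities under record duplication (coefficients and clustered sandwich
  invariant, naive SE shrinking by √2) hold under Breslow and are tested
  there.
* **Variance.** Naive covariance = inverse observed information; robust
  covariance = A⁻¹BA⁻¹ with B the outer product of per-woman sums of
  Efron-aware score residuals. The implementation reproduces
  `survival::coxph(..., cluster=id, ties="efron")` to ~7 digits and, in
  the absence of ties, a general-purpose Python Cox implementation to
  ~1e−10.
* **Age** enters linearly in the log hazard, centered at 59.5 years purely
  for conditioning; hazard ratios and predicted risks are invariant to the
  center (tested to 1e−8).
* **Separation.** A coefficient path that degenerates the information
  matrix (e.g. a level with no events) stops at a bounded estimate with an
  explicit warning; a design that is rank-deficient from the start raises.
* **Baseline hazard.** Λ0 steps are `d_k / Σ_at-risk exp(β′Z)` at each
  distinct event residual-time; with β = 0 this is exactly Nelson–Aalen.

### Reporting

The hazard-ratio table reports person-time per covariate *level* by
interval decomposition: a record occupies its level from its landmark to
the next landmark (or to end of follow-up), so the women-years column sums
to total follow-up, matching the convention of published screening-cohort
tables; the event is attributed to the level occupied at diagnosis. (The
alternative — summing stacked residual times — multiply counts follow-up
and cannot reproduce published margins.)

Interaction screening refits the model with all cross-level product
columns for each candidate pair and reports a robust multivariate Wald
test; empty interaction cells and collinear candidates are reported as NA
with the reason. Proportional hazards are inspected via log(−log S(t))
against log t per level (Kaplan–Meier based); the parallelism summary is
the range of the vertical spread over grid points where every level's
survivor function lies in [0.05, 0.95] — outside that band the transform
is dominated by KM tail noise.

## Validation

The cohort is split at the woman level, 60% estimation / 40% validation,
reproducibly from a seed. All validation quantities use predictions from
each woman's **baseline** (first-visit) profile.

* **Calibration.** E/O per horizon: E = mean predicted τ-year risk over
  validation women; O-rate = Kaplan–Meier cumulative incidence at τ from
  woman-level (end_time, event). The 95% CI is the standardized-mortality-
  ratio log-normal form `ratio · exp(±1.96/√O)` with O the observed event
  count (exact-Poisson variant behind `method="poisson"`). Subgroup
  calibration repeats this within levels of a baseline covariate at a
  chosen horizon (default 10 years); zero-event levels are retained as NA
  rows.
* The SMR interval models only the Poisson noise of the observed count.
  When the estimation subcohort is small (≈200 events) the sampling noise
  of E — driven by coefficient uncertainty — is comparable, and the SMR
  interval undercovers at mid horizons. Two Monte-Carlo alternatives are
  provided: `eo_bootstrap_ci` (woman-level bootstrap of the validation
  side, capturing KM-tail noise) and `eo_monte_carlo_ci`, which adds an
  estimation-cohort cluster bootstrap with refitting so both noise
  components of the ratio — measured to be comparably sized at the default
  scale — enter the interval.
* Subgroup calibration at long horizons can be artefactual for the oldest
  entry band: women entering at 65–69 age out of screening within ~4–6
  years, so their within-band KM at a 10-year horizon sits frozen at the
  last observable time and E/O is inflated by construction (the KM helper
  warns when a horizon exceeds the band's support). Interpret Table-4-style
  old-age rows at long horizons accordingly.
* **Discrimination.** AUC at horizon τ among observable women: cases have
  an event by τ; controls are event-free with follow-up ≥ τ; women
  censored event-free before τ are excluded (inverse-censoring weighting
  is out of scope; it reportedly changes little). Ties get half credit.
  The CI is Hanley–McNeil with Q1 = A/(2−A), Q2 = 2A²/(1+A), clipped to
  [0, 1]. AUC is exactly invariant to monotone rescaling of the scores.
* Horizons beyond the support of Λ0 are evaluated at its last step and
  flagged — explicit non-extrapolation rather than a silent tail model.
* Multiple horizons are reported without multiplicity adjustment.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
configurable scale:

* **Entry and attendance.** Entry age drawn from the four 5-year bands
  with the published no-cancer mix (53.0/21.5/19.0/6.6%), uniform within
  band and below the age-69 invitation limit; biennial visits continue
  until age 69, non-continuation (per-round probability 1 − 0.806), or
  diagnosis. Non-continuation folds together drop-out, migration,
  administrative end of study, and death, which a screening registry
  cannot distinguish. The continuation probability was tuned once so mean
  follow-up ≈ 7.5 years.
* **Covariates.** Family history is fixed at entry (prevalence 13.86%).
  BBD starts from the published baseline mix and progresses from "none"
  with small per-round probabilities (0.4/0.2/0.04% to unknown-biopsy,
  non-proliferative, proliferative); non-none BBD is absorbing — a biopsy
  history cannot be undone. Previous mammographic features are likewise a
  *history* variable: prevalent at entry per the published mix (28%
  non-none), acquired at 3% per round, persistent thereafter. (A fully
  transient per-visit feature process is available via
  `feature_incidence=None`; under it the landmark association is
  structurally attenuated relative to the generating hazard ratio —
  measured, e.g., 2.52 → ≈1.6 for calcifications — which is why history
  semantics are the default.)
* **Events.** Piecewise-constant hazard λ0·exp(β′Z(s_k)) on each two-year
  interval, using the covariates of the visit opening the interval, with
  exact inversion sampling; the final interval after the last attended
  visit is the two-year censoring window. Generating log hazard ratios
  default to the published point estimates; the age effect defaults to 0
  so every recovery check has a known truth.
* **Baseline hazard.** `calibrate_baseline` matches a target marginal
  incidence (default 2.18 events per 1,000 women-years): a first-order
  estimate divides the target by the person-time-weighted mean relative
  hazard, then two simulation rounds absorb the small exposure truncation
  caused by events themselves. The shipped default (0.0015433 per
  woman-year for the reference profile) realizes 2.172/1,000 at n =
  500,000.

What the generator does **not** emulate: calendar time (no period effects,
no administrative censoring date), recall/false-positive workflow, breast
density, genetic risk, death as a competing risk, incident family history,
feature-category upgrades to "multiple". Passing tests therefore show that
the estimation and validation machinery is correct and calibrated under
the stated generative structure — not that the published effect sizes are
externally valid.

## Desk-scale phenomena worth knowing

Measured properties of the default 60,000-woman experiment that shape what
the tests assert:

* **Thin long-horizon support.** Only entrants aged ~50–51 who attend ~9
  rounds are observable at 18–20 years (≈1.3% of women). The Breslow
  support typically ends at 17–20 years and the validation KM tail at 20
  years rests on a few hundred women, so the 20-year E/O has Monte-Carlo
  sd ≈ 0.13 — wider than its own SMR interval. Comparisons at 20 years use
  the bootstrap interval.
* **Age-coefficient noise at long-horizon AUC.** With a true age effect of
  0, the fitted age coefficient (SE ≈ 0.01) still spreads predictions
  across the 19-year age range; at τ = 20 the control group is an
  age-extreme subset, so single-cohort AUC at 18–20 years has sd ≈ 0.1 and
  can fall below 0.5 by chance. The direction check therefore averages
  over 10 replicate cohorts (n = 30,000).
* **Rare-level small-sample bias.** Proliferative BBD (0.45% prevalence)
  yields ~15 events per 20,000-woman cohort; its fitted log hazard ratio
  is noticeably variable and slightly biased upward in the mean, as
  expected for a near-separated level. Replicate-mean recovery within 3%
  is asserted for the well-populated levels.
* **Coverage.** Pooled over the nine factor levels, 95% robust-CI coverage
  across 200 replicates at n = 20,000 is ≈ 93%; E/O CI coverage of 1.0 is
  asserted at the 2-year horizon, where the Poisson term dominates the SMR
  interval (see above for why mid-horizon SMR intervals undercover at this
  scale).

## Problem sizes used by the test suite

Chosen to keep the full suite in the tens of minutes on one CPU while
leaving every assertion at its stated tolerance: the headline experiment
at n = 60,000 (one cohort, fixed seed); coverage at 200 replicates of
n = 20,000; discrimination direction at 10 replicates of n = 30,000;
interaction type-I error at 30 replicates of n = 2,500; module unit tests
at n ≤ 6,000.

## Known limitations

* The partly conditional model is exactly specified only if the hazard
  given the landmark profile is proportional on the residual-time axis;
  covariate drift after the landmark makes this an approximation whose
  error grows with horizon and with drift rates (kept small by the history
  semantics of the default generator, as in the real predictors).
* Λ0 is pooled across landmarks; per-landmark baseline hazards are not
  modelled.
* No competing-risk adjustment: "risk" is risk of diagnosis while under
  the program's observation, not lifetime risk net of mortality.
* The split-sample validation is internal; nothing here substitutes for
  external validation on an independent program.
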