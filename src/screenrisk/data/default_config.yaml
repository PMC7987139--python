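# Default synthetic-cohort configuration (version 1).
#
# Marginals emulate the target screening population: entry-age mix and
# covariate prevalences from its baseline characteristics, generating hazard
# ratios from its published model, baseline hazard calibrated so the marginal
# incidence is 2.18 events per 1,000 women-years, and per-round continuation
# tuned so mean follow-up is ~7.5 years.
n_women: 60000
seed: 0
entry_age_weights:
  50-54: 0.5296
  55-59: 0.2146
  60-64: 0.1901
  65-69: 0.0656
per_round_continuation: 0.806
famhist_prev: 0.1386
bbd_baseline_probs:
  none: 0.7464
  prior_biopsy_unknown: 0.2172
  non_proliferative: 0.0320
  proliferative: 0.0045
bbd_progression:
  prior_biopsy_unknown: 0.004
  non_proliferative: 0.002
  proliferative: 0.0004
feature_probs:
  none: 0.7199
  mass: 0.1812
  calcifications: 0.0271
  asymmetry: 0.0281
  architectural_distortion: 0.0104
  multiple: 0.0333
feature_persistence: 1.0
feature_incidence: 0.03
true_log_hr:
  family_history: 0.5128236264286637    # ln 1.67
  bbd:prior_biopsy_unknown: 0.3074846997479607   # ln 1.36
  bbd:non_proliferative: 0.34358970439007686      # ln 1.41
  bbd:proliferative: 1.1052568313867783          # ln 3.02
  feature:mass: 0.27763173659827955               # ln 1.32
  feature:calcifications: 0.9242589015233319     # ln 2.52
  feature:asymmetry: 0.5068176023684519          # ln 1.66
  feature:architectural_distortion: 0.7275486072772777  # ln 2.07
  feature:multiple: 0.62057648772511           # ln 1.86
  age: 0.0
baseline_hazard: 0.0015433
age_center: 59.5
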