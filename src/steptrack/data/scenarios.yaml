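# Named generator presets.
#
# reference    -- a small oncology wear-study-like cohort: ECOG-linked
#                 activity levels, a treatment-day activity dip, negative
#                 symptom-activity coupling, and adherence drop-off tuned
#                 so roughly two-thirds of patients meet the inclusion rule.
# null         -- no group effect, zero symptom coupling, perfect wear;
#                 used for type-I-error calibration of the group tests.
# high-dropout -- same activity structure as `reference` with a much
#                 steeper wear decay, for adherence stress tests.
reference:
  n_patients: 40
  ecog_probs: {0: 0.63, 1: 0.37}
  group_log_mean_steps: {0: 8.8570, 1: 8.5951}
  between_patient_sd: 0.30
  nb_dispersion: 8.0
  treatment_day_effect: 0.35
  recovery_days: 4
  symptom_coupling: -0.8
  symptom_base_loc: -0.8
  improvement_prob_base: 0.55
  improvement_shift: 0.8
  improvement_activity_gain: 4.0
  wear_prob_start: 0.78
  wear_decay_per_day: 0.16
  partial_day_prob: 0.01
  seed: 0
"null":
  n_patients: 27
  ecog_probs: {0: 0.5, 1: 0.5}
  group_log_mean_steps: {0: 8.6, 1: 8.6}
  between_patient_sd: 0.30
  nb_dispersion: 8.0
  treatment_day_effect: 1.0
  recovery_days: 0
  symptom_coupling: 0.0
  symptom_base_loc: -0.8
  improvement_prob_base: 0.55
  improvement_shift: 0.8
  improvement_activity_gain: 4.0
  wear_prob_start: 1.0
  wear_decay_per_day: 0.0
  partial_day_prob: 0.0
  seed: 0
high-dropout:
  n_patients: 40
  ecog_probs: {0: 0.63, 1: 0.37}
  group_log_mean_steps: {0: 8.8570, 1: 8.5951}
  between_patient_sd: 0.30
  nb_dispersion: 8.0
  treatment_day_effect: 0.35
  recovery_days: 4
  symptom_coupling: -0.8
  symptom_base_loc: -0.8
  improvement_prob_base: 0.55
  improvement_shift: 0.8
  improvement_activity_gain: 4.0
  wear_prob_start: 0.70
  wear_decay_per_day: 0.30
  partial_day_prob: 0.01
  seed: 0
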