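# Built-in parameter set: Dutch economic evaluation of Internet-based CBT
# for treatment-induced menopausal symptoms in breast cancer survivors.
#
# Utilities and first-cycle response proportions come from a three-arm RCT
# (guided iCBT / self-managed iCBT / waiting list, n = 254); recurrence and
# mortality probabilities from Dutch registries (annual); healthcare
# utilization costs per provider category per 6-month cycle from the trial's
# medical-consumption questionnaire.  Note the trial reported HIGHER
# utilization costs in the reduced-symptoms state than in the symptomatic
# state; the provider blocks below carry that assignment.
utilities:
  u_ms: 0.83
  u_red: 0.85
  u_rec: 0.73
  u_dead: 0.0
transitions:
  p_response:
    guided: 0.44
    self_managed: 0.39
    waitlist: 0.23
  p_to_recurrence: 0.01     # annual, from either non-recurrence alive state
  p_rec_death: 0.04         # annual, recurrence to death
  background_mortality: [0.0007, 0.0012]   # annual, ages 47 -> 51
  probs_are_annual: true
  mortality_is_per_cycle: false
costs:
  intervention_cost:        # EUR per patient, one-off, incl. 44% overhead
    guided: 226.09
    self_managed: 47.92
    waitlist: 0.0
  provider_costs:           # EUR per 6-month cycle
    menopausal_symptoms:
      general_practitioner: 45.38
      medical_specialist: 129.28
      psychologist_psychiatrist: 43.37
      social_worker: 9.47
      physiotherapist: 158.05
      lymphedema_therapist: 93.75
      dietitian: 4.99
      alternative_medicine: 19.11
    reduction:
      general_practitioner: 48.70
      medical_specialist: 152.00
      psychologist_psychiatrist: 35.20
      social_worker: 3.25
      physiotherapist: 207.78
      lymphedema_therapist: 106.01
      dietitian: 18.74
      alternative_medicine: 8.96
  recurrence_costs:         # EUR per year, split over two 6-month cycles
    year1:
      inpatient_outpatient: 10263.00
      drugs: 1918.00
    year2:
      inpatient_outpatient: 2294.00
      drugs: 65.00
  rec_post_fraction: 0.0    # no maintenance cost beyond recurrence year 2
bia:
  annual_population: 600
  mix_weights:
    guided: 0.5
    self_managed: 0.5
psa_specs:
  utilities.u_ms: {kind: beta, mean: 0.83, se: 0.013}
  utilities.u_red: {kind: beta, mean: 0.85, se: 0.017}
  utilities.u_rec: {kind: beta, mean: 0.73, se: 0.020}
  transitions.p_response: {kind: dirichlet, mean: 0.0, ess: 85.0}
  transitions.p_to_recurrence: {kind: fixed, mean: 0.01}
  transitions.p_rec_death: {kind: fixed, mean: 0.04}
discount_effects: 0.015
discount_costs: 0.04
cycle_length: 0.5
n_cycles: 10
cohort_size: 1000
baseline_age: 47.0
wtp: 30000.0
effect_duration_cycles: null
cost_se_fraction: 0.20
accrual: begin
response_before_competing_risks: false
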