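# Base-case parameter set: HIV-infected women, CD4 200-500 cells/mL,
# single lifetime screen at age 38.  Monthly probabilities; costs in 2014 USD.
# `ranges` lists [min, max] for the one-way sensitivity analysis in table
# row order; `scenarios` holds the CD4-stratified overrides (cells the
# scenario analysis leaves blank inherit the base case).
start_age: 38
prev_disease: 0.22
split_diseased:
  lsil: 0.0
  hsil: 0.952
  local: 0.020
  regional: 0.024
  distant: 0.004
split_nondiseased:
  normal: 0.902
  lsil: 0.098
ltfu_2visit: 0.32
ltfu_3visit: 0.48
smr: 1.77
cancer_mortality_monthly:
  local: 0.004
  regional: 0.021
  distant: 0.063
progression_monthly:
  normal_lsil: 0.001
  lsil_hsil: 0.003
  hsil_local: 0.002
  local_regional: 0.003
  regional_distant: 0.003
regression_monthly:
  lsil_normal: 0.003
  hsil_lsil: 0.0
  hsil_normal: 0.0
treatment_effectiveness: 0.9
cure_monthly: 0.15
side_effect_monthly: 0.01
p_side_effect_major: 0.16
p_cryo_given_treatment: 0.8
discount_monthly: 0.0025
test_performance:
  Pap:      {sensitivity: 0.74, specificity: 0.98}
  VIA:      {sensitivity: 0.61, specificity: 0.63}
  HPV:      {sensitivity: 0.81, specificity: 0.55}
  VIA+HPV:  {sensitivity: 0.58, specificity: 0.84}
  VIA+Pap:  {sensitivity: 0.51, specificity: 0.99}
  HPV+Pap:  {sensitivity: 0.63, specificity: 0.99}
unit_costs:
  societal:
    screening:    {pap: 39.0, via: 18.0, hpv: 32.0}
    treatment:    {cryotherapy: 48.0, colposcopy: 160.0, leep: 86.0}
    side_effects: {major: 974.0, minor: 203.0}
    cancer_care:  {local: 1135.0, regional: 6447.0, distant: 5107.0, palliative_monthly: 196.0}
  clinic:
    screening:    {pap: 24.0, via: 10.0, hpv: 18.0}
    treatment:    {cryotherapy: 12.0, colposcopy: 109.0, leep: 20.0}
    side_effects: {major: 847.0, minor: 178.0}
    cancer_care:  {local: 112.0, regional: 149.0, distant: 144.0, palliative_monthly: 145.0}
ranges:
  start_age: [30, 46]
  prev_disease: [0.18, 0.27]
  split_diseased.hsil: [0.762, 1.0]
  split_diseased.local: [0.016, 0.024]
  split_diseased.regional: [0.019, 0.029]
  split_diseased.distant: [0.003, 0.005]
  split_nondiseased.lsil: [0.078, 0.118]
  split_nondiseased.normal: [0.722, 1.0]
  ltfu_2visit: [0.0, 0.4]
  ltfu_3visit: [0.3, 0.6]
  smr: [1.42, 2.12]
  cancer_mortality_monthly.local: [0.003, 0.005]
  cancer_mortality_monthly.regional: [0.017, 0.025]
  cancer_mortality_monthly.distant: [0.051, 0.076]
  progression_monthly.normal_lsil: [0.000, 0.002]
  progression_monthly.lsil_hsil: [0.002, 0.004]
  progression_monthly.hsil_local: [0.001, 0.003]
  progression_monthly.local_regional: [0.002, 0.004]
  progression_monthly.regional_distant: [0.002, 0.004]
  regression_monthly.lsil_normal: [0.002, 0.004]
  regression_monthly.hsil_lsil: [0.000, 0.001]
  regression_monthly.hsil_normal: [0.000, 0.001]
  treatment_effectiveness: [0.7, 1.0]
  cure_monthly: [0.12, 0.18]
  side_effect_monthly: [0.00, 0.02]
  p_side_effect_major: [0.13, 0.20]
  test_performance.Pap.sensitivity: [0.59, 0.89]
  test_performance.VIA.sensitivity: [0.49, 0.73]
  test_performance.HPV.sensitivity: [0.65, 0.97]
  test_performance.VIA+HPV.sensitivity: [0.46, 0.70]
  test_performance.VIA+Pap.sensitivity: [0.41, 0.61]
  test_performance.HPV+Pap.sensitivity: [0.50, 0.76]
  test_performance.Pap.specificity: [0.78, 1.0]
  test_performance.VIA.specificity: [0.50, 0.76]
  test_performance.HPV.specificity: [0.44, 0.66]
  test_performance.VIA+HPV.specificity: [0.67, 1.0]
  test_performance.VIA+Pap.specificity: [0.79, 1.0]
  test_performance.HPV+Pap.specificity: [0.79, 1.0]
  cost.screening.pap: [31.0, 47.0]
  cost.screening.via: [14.0, 22.0]
  cost.screening.hpv: [26.0, 38.0]
  cost.treatment.cryotherapy: [38.0, 58.0]
  cost.treatment.colposcopy: [128.0, 192.0]
  cost.treatment.leep: [69.0, 103.0]
  cost.side_effects.major: [779.0, 1169.0]
  cost.side_effects.minor: [162.0, 244.0]
  cost.cancer_care.local: [908.0, 1362.0]
  cost.cancer_care.regional: [5158.0, 7736.0]
  cost.cancer_care.distant: [4086.0, 6128.0]
  cost.cancer_care.palliative_monthly: [157.0, 235.0]
scenarios:
  cd4_low:
    prev_disease: 0.33
    # printed pair sums to 1.001; renormalized where consumed
    split_nondiseased: {normal: 0.832, lsil: 0.169}
    smr: 2.54
    test_performance:
      Pap: {sensitivity: 0.76, specificity: 0.93}
      VIA: {sensitivity: 0.76, specificity: 0.62}
      HPV: {sensitivity: 0.92, specificity: 0.46}
  cd4_high:
    prev_disease: 0.12
    split_diseased: {lsil: 0.0, hsil: 1.0, local: 0.0, regional: 0.0, distant: 0.0}
    split_nondiseased: {normal: 0.975, lsil: 0.025}
    smr: 1.0
    progression_monthly:
      normal_lsil: 0.000
      lsil_hsil: 0.001
      hsil_local: 0.002
    test_performance:
      Pap: {sensitivity: 0.61, specificity: 0.98}
      VIA: {sensitivity: 0.52, specificity: 0.73}
      HPV: {sensitivity: 0.83, specificity: 0.62}
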