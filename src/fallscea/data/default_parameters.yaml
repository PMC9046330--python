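# Default model inputs: 12-month supervised exercise vs usual care for falls
# and fracture prevention in men on androgen deprivation therapy (ADT) for
# non-metastatic prostate cancer.  All costs are 2019 AUD, health-system
# perspective.  Each uncertain parameter carries its published mean, 95% CI
# and the distribution family used for probabilistic sensitivity analysis.

settings:
  start_age: 68            # mean age at model commencement, years
  horizon_years: 3         # 1 year of training + 2-year sustained effect
  cycle_months: 3          # recovery period after a fall injury
  discount_annual: 0.05    # annual discount rate, costs and QALYs
  wtp: 50000               # willingness-to-pay, AUD per QALY

parameters:
  # ---- transition probabilities (12-month) ----
  p_fall_year1:
    mean: 0.36
    ci_low: 0.29
    ci_high: 0.43
    family: beta
    units: probability/year
    source: falls and frailty study of prostate-cancer survivors on ADT
  p_fall_recurrent:
    mean: 0.65
    ci_low: 0.53
    ci_high: 0.77
    family: beta
    units: probability/year
    source: falls and frailty study of prostate-cancer survivors on ADT
  rr_fall_exercise:
    mean: 0.76
    ci_low: 0.70
    ci_high: 0.81
    family: lognormal
    units: relative risk
    source: systematic review, exercise for falls prevention in the community
  p_fracture_annual:
    mean: 0.12
    ci_low: 0.09
    ci_high: 0.15
    family: beta
    units: probability
    source: systematic review, exercise for falls prevention in the community
  rr_fracture_exercise:
    mean: 0.44
    ci_low: 0.25
    ci_high: 0.76
    family: lognormal
    units: relative risk
    source: systematic review, exercise for falls prevention in the community
  p_fx_major:
    mean: 0.62
    ci_low: 0.58
    ci_high: 0.66
    family: beta
    units: proportion of fractures
    source: population-based cohort of men with prostate cancer on ADT
  p_fx_minor:
    mean: 0.38
    ci_low: 0.34
    ci_high: 0.42
    family: beta
    units: proportion of fractures
    source: population-based cohort of men with prostate cancer on ADT
  p_nonfx_injury:
    mean: 0.88
    ci_low: 0.87
    ci_high: 0.89
    family: beta
    units: probability per non-fracture fall
    source: systematic review, exercise for falls prevention in the community
  rr_injury_exercise:
    mean: 0.70
    ci_low: 0.54
    ci_high: 0.92
    family: lognormal
    units: relative risk
    source: meta-analysis, exercise and fall-related injuries
  p_inj_major:
    mean: 0.06
    ci_low: 0.055
    ci_high: 0.065
    family: beta
    units: proportion of non-fracture injuries
    source: population-based cohort of men with prostate cancer on ADT
  p_inj_minor:
    mean: 0.94
    ci_low: 0.93
    ci_high: 0.95
    family: beta
    units: proportion of non-fracture injuries
    source: population-based cohort of men with prostate cancer on ADT
  p_death_fall_60_64:
    mean: 0.023
    ci_low: 0.015
    ci_high: 0.031
    family: beta
    units: probability of death given a major fall event, ages 60-64
    source: falls cost-effectiveness model, fall-death case fatality by age
  p_death_fall_65_69:
    mean: 0.043
    ci_low: 0.033
    ci_high: 0.053
    family: beta
    units: probability of death given a major fall event, ages 65-69
    source: falls cost-effectiveness model, fall-death case fatality by age
  p_death_fall_70_74:
    mean: 0.065
    ci_low: 0.062
    ci_high: 0.068
    family: beta
    units: probability of death given a major fall event, ages 70-74
    source: falls cost-effectiveness model, fall-death case fatality by age

  # ---- costs (2019 AUD, per event / per participant) ----
  c_fx_major:
    mean: 20724
    ci_low: 20082
    ci_high: 21366
    family: gamma
    units: AUD per major fracture
    source: osteoporotic fracture costing study, converted to 2019 AUD
  c_fx_minor:
    mean: 8797
    ci_low: 8524
    ci_high: 9070
    family: gamma
    units: AUD per minor fracture
    source: osteoporotic fracture costing study, converted to 2019 AUD
  c_inj_major:
    mean: 10040
    ci_low: 9729
    ci_high: 10351
    family: gamma
    units: AUD per major non-fracture injury
    source: hospital pricing (NEP 2019-20) plus primary/community care costs
  c_inj_minor:
    mean: 1115
    ci_low: 1080
    ci_high: 1150
    family: gamma
    units: AUD per minor non-fracture injury
    source: hospital pricing (NEP 2019-20) plus primary/community care costs
  c_intervention:
    mean: 767
    ci_low: 743
    ci_high: 791
    family: gamma
    units: AUD per participant
    source: MBS-based costing of AEP-supervised group exercise (see components)

  # ---- health-state utilities ----
  u_baseline:
    mean: 0.79
    ci_low: 0.78
    ci_high: 0.80
    family: beta
    units: utility
    source: PORPUS-U standard-gamble utilities, men on RT + adjuvant ADT
  u_fx_major:
    mean: 0.475
    ci_low: 0.47
    ci_high: 0.49
    family: beta
    units: utility
    source: AusICUROS EQ-5D utilities, major osteoporotic fracture
  u_fx_minor:
    mean: 0.565
    ci_low: 0.55
    ci_high: 0.59
    family: beta
    units: utility
    source: AusICUROS EQ-5D utilities, non-MOF fracture
  u_inj_major:
    mean: 0.47
    ci_low: 0.46
    ci_high: 0.48
    family: beta
    units: utility
    source: utility decrement for moderate traumatic brain injury
  u_inj_minor:
    mean: 0.765
    ci_low: 0.76
    ci_high: 0.80
    family: beta
    units: utility
    source: EQ-5D quality of life of community-dwelling seniors after falls
  u_recurrent_control:
    mean: 0.72
    ci_low: 0.70
    ci_high: 0.74
    family: beta
    units: utility
    source: EQ-5D quality of life, recurrent falls / fear of falling
  u_recurrent_exercise:
    mean: 0.74
    ci_low: 0.72
    ci_high: 0.76
    family: beta
    units: utility
    source: systematic review, exercise to reduce fear of falling

# Line items behind c_intervention (2019 AUD per participant).
intervention_cost_components:
  gp_eligibility_consult: 38          # MBS item 23, level B GP consultation
  registration_and_admin: 15          # 30 min clerk time + phone calls
  aep_pre_program_consult: 81         # MBS item 81110
  supervised_group_sessions: 633      # 50 weeks, MBS item 10953, groups of 10

# Annual all-cause male death probabilities by single year of age.
# External national life-table defaults; override-able.
background_mortality_file: background_mortality.csv
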