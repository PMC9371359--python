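schema_version: 1
incidence:
  pd:
    40-49: 0.0
    50-59: 0.000211
    60-69: 0.000995
    70-79: 0.003005
    80+: 0.003699
  dm:
    40-49: 0.00964
    50-59: 0.00964
    60-69: 0.01906
    70-79: 0.01906
    80+: 0.01637
  pd_given_dm:
    40-49: 0.0
    50-59: 0.000464
    60-69: 0.001542
    70-79: 0.004658
    80+: 0.005733
mortality:
  dm:
    40-49: 0.0151
    50-59: 0.02195
    60-69: 0.03931
    70-74: 0.05288
    75+: 0.0815
  other:
    40-49: 0.00266
    50-59: 0.00507
    60-69: 0.01028
    70-79: 0.02677
    80+: 0.05722
  pd_stage:
    hy1: 0.01
    hy2: 0.048
    hy3: 0.08
    hy4: 0.199
transition_rates:
  pd:
    lam1: 0.3237
    lam2: 0.068
    lam3: 0.3192
  pd_dm:
    lam1: 0.4369
    lam2: 0.1462
    lam3: 0.3192
effects:
  m1: 0.947
  m2: 0.239
  m3: 0.206
  dm_mortality_factor: 0.88
  dm_utility_increment: 0.08
  pd_incidence_reduction: 0.0
costs:
  pd_medical:
    hy1: 21821.9
    hy2: 69074.2
    hy3: 71969.3
    hy4: 133558.1
  pddm_medical:
    hy1: 21821.9
    hy2: 90217.1
    hy3: 77079.1
    hy4: 148740.9
  home_care:
    hy1: 0.0
    hy2: 0.0
    hy3: 22220.0
    hy4: 22220.0
  pd_productivity_loss:
    hy1: 17261.2
    hy2: 52185.1
    hy3: 95538.9
    hy4: 54593.7
  dm_medical:
    40-49: 43903.6
    50-59: 58903.6
    60-69: 73903.6
    70-79: 88903.6
    80+: 103903.6
  dm_productivity_loss:
    40-49: 635049.0
    50-59: 605055.6
    60-69: 481893.0
    70+: 0.0
  exenatide_annual: 33926.8
utilities:
  normal:
    40-64: 0.92
    65+: 0.84
  pd:
    hy1: 0.708
    hy2: 0.678
    hy3: 0.622
    hy4: 0.499
  dm_decrement: 0.04
  dm_annual_decline: 0.003
economics:
  discount_rate: 0.03
  horizon_cycles: 50
  cycle_length_years: 1.0
  cohort_size: 1000.0
  entry_age: 40
  dm_prevalence_at_entry: 0.0605
  wtp_gdp: 839558.0
options:
  rate_conversion: exponential
  reward_timing: start
  exenatide_coverage:
  - dm
  - pd
  - pd_dm
  dm_cost_accrual: per_arm
  pddm_cost_adds_dm_medical: false
  dm_decline_by_model_time: true
  use_printed_pddm_lambda3: false
sa_ranges:
  incidence.pd.50-59:
  - 0.000193
  - 0.000229
  incidence.pd.60-69:
  - 0.000773
  - 0.001218
  incidence.pd.70-79:
  - 0.002577
  - 0.003435
  incidence.pd.80+:
  - 0.00328
  - 0.004118
  incidence.dm.40-49:
  - 0.00911
  - 0.01017
  incidence.dm.50-59:
  - 0.00911
  - 0.01017
  incidence.dm.60-69:
  - 0.01699
  - 0.02112
  incidence.dm.70-79:
  - 0.01699
  - 0.02112
  incidence.dm.80+:
  - 0.01419
  - 0.01854
  incidence.pd_given_dm.50-59:
  - 0.000371
  - 0.000578
  incidence.pd_given_dm.60-69:
  - 0.001453
  - 0.001711
  incidence.pd_given_dm.70-79:
  - 0.004387
  - 0.005169
  incidence.pd_given_dm.80+:
  - 0.005401
  - 0.006362
  mortality.dm.40-49:
  - 0.0099
  - 0.0203
  mortality.dm.50-59:
  - 0.0123
  - 0.035
  mortality.dm.60-69:
  - 0.0273
  - 0.0547
  mortality.dm.70-74:
  - 0.0486
  - 0.058
  mortality.dm.75+:
  - 0.0778
  - 0.0863
  mortality.other.40-49:
  - 0.0017
  - 0.0035
  mortality.other.50-59:
  - 0.0038
  - 0.0065
  mortality.other.60-69:
  - 0.007
  - 0.0148
  mortality.other.70-79:
  - 0.0164
  - 0.0393
  mortality.other.80+:
  - 0.0432
  - 0.0628
  effects.dm_mortality_factor:
  - 0.86
  - 0.9
  effects.m1:
  - 0.947
  - 0.99
  effects.m2:
  - 0.2
  - 0.32
  effects.m3:
  - 0.17
  - 0.28
  costs.pd_medical.hy2:
  - 17470.5
  - 254268.4
  costs.pd_medical.hy3:
  - 22218.5
  - 152150.8
  costs.pd_medical.hy4:
  - 50890.6
  - 172994.6
  costs.pddm_medical.hy2:
  - 24685.3
  - 264341.0
  costs.pddm_medical.hy3:
  - 43927.4
  - 123334.5
  costs.pd_productivity_loss.hy1:
  - 5218.5
  - 29304.0
  costs.pd_productivity_loss.hy2:
  - 40142.4
  - 64227.8
  costs.pd_productivity_loss.hy3:
  - 83496.2
  - 107581.6
  costs.pd_productivity_loss.hy4:
  - 42550.9
  - 66636.4
  costs.dm_medical.40-49:
  - 39887.8
  - 47919.4
  costs.dm_medical.50-59:
  - 54887.8
  - 62919.4
  costs.dm_medical.60-69:
  - 69887.8
  - 77919.4
  costs.dm_medical.70-79:
  - 84887.8
  - 92919.4
  costs.dm_medical.80+:
  - 99887.8
  - 107919.4
  utilities.pd.hy1:
  - 0.638
  - 0.778
  utilities.pd.hy2:
  - 0.608
  - 0.748
  utilities.pd.hy3:
  - 0.552
  - 0.692
  utilities.pd.hy4:
  - 0.429
  - 0.569
  utilities.dm_decrement:
  - 0.0352
  - 0.0448
  utilities.dm_annual_decline:
  - 0.00214
  - 0.00387
  utilities.normal.40-64:
  - 0.74
  - 1.0
  utilities.normal.65+:
  - 0.39
  - 1.0
  effects.dm_utility_increment:
  - 0.06
  - 0.1
  economics.discount_rate:
  - 0.0
  - 0.05
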