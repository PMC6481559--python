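# Small-effect standard scenario: cohort of 15,000, all log hazard ratios
# 0.2, 50% of x2 missing at random, administrative censoring at the time
# giving ~10% events (see cohortmi.simulate.calibrate_censor_time).
n_cohort: 15000
lam: 1.0
beta_x1: 0.2
beta_x2: 0.2
beta_z: 0.2
covariate_corr: 0.5
p_x2: 0.5
p_z: 0.5
missing_frac_x2: 0.5
gamma_z: 0.5
gamma_d: 0.5
gamma_zd: 0.25
censor_time: 0.4063
variant: standard
seed: 1
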