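# Reference simulated-study configuration.
#
# The generator emulates the observational setting: 270 cities observed
# 2007-2020, three pilot waves (2012/2013/2014, 10% of cities each, so the
# treated city-year share is 0.171), a direct policy effect of 0.12 on the
# index scale and three mediator paths contributing a further 0.023
# (total effect 0.143).
seed: 1

dgp:
  n_cities: 270
  n_years: 14
  start_year: 2007
  theta_true: 0.12
  adoption_waves: [[2012, 0.10], [2013, 0.10], [2014, 0.10]]
  confounder_dim: 10
  confounding_strength: 1.0
  nonlinear_nuisance: true
  mediator_paths:
    EEQ: [0.028, 0.143]
    ISL: [0.205, 0.054]
    HWS: [0.773, 0.010]
  mediator_noise_sd:
    EEQ: 0.10
    ISL: 1.0
    HWS: 3.0
  seed: 20070

prep:
  add_squares: true
  fe_year: true
  fe_city: true

dml:
  n_folds: 5                 # 1:4 holdout:training split
  learner: random_forest
  learner_params: {n_estimators: 100}
  n_repeats: 1

mediators: [EEQ, ISL, HWS]
subgroup_vars: [region, size, regulation, batch]
winsor_presets: [[0.01, 0.99], [0.05, 0.95]]
fold_presets: [4, 8]
swap_learner: gradient_boosting
n_boot: 200
boot_learner: linear
out_dir: scratch/study_out
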