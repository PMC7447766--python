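# Demo pipeline: small synthetic cohort end to end.
#   pdprog run-all --config configs/demo.yaml
seed: 1
out_dir: out/demo
simulate:
  n_subjects: 300
  missingness_rate: 0.02
impute:
  imputer: rbm
  epochs: 120
mixed: {}
tgl:
  theta: {theta1: 0.1, theta2: 0.1, theta3: 0.5}
  max_iter: 500
evaluate:
  n_outer: 10
  holdout: 0.25
  inner_folds: 5
  models: [mixed-bio, mixed-cog, tgl]
survival:
  scale: onset
  groups: [gba, sex]
  cox: [sex, gba, apoe4, onset_age_years]
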