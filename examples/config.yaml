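# Demo configuration for the CLI (zebra simulate / run-all).
# Every stochastic stage takes its seed from here; outputs embed the
# config hash so runs are traceable.
cohort:
  n_cases_pos: 10
  n_cases_neg: 10
  glomeruli_per_case: [3, 5]
  target_fraction_range: [0.10, 0.30]
  fraction_positive_glomeruli: 0.74
  stain: HE
  source_mpp: 0.2208
  noise_level: 4.0
  seed: 0
tiling:
  tile_px: 512
  target_mpp: 0.5
  stride_px: 512
cls:
  model: sgd_logistic
  epochs: 5
  batch_size: 32
  learning_rate: 0.05
  augment: false
  seed: 0
seg:
  model: sgd_logistic
  epochs: 3
  n_sample_px: 2000
  threshold: 0.5
  seed: 0
k_folds: 5
glomerulus_rule: any_positive
cutoff: null  # null -> Youden-selected on case mean ZS
n_resamples: 1000
seed: 0
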