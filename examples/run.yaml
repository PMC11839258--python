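# Full-pipeline configuration: synthetic cohort, default analysis settings.
seed: 1
input:
  kind: synthetic          # or "csv" with cohort_csv / metadata_csv paths
  synthetic:
    n_subjects: 6
    duration_s: 20.0
    noise_sd_mm: 1.0
decomposition:
  k_retained: 5
  cutoff_hz: 7.0
  filter_order: 3
  loo: true
stability:
  mode: fixed              # "adaptive" re-selects (tau, m) via AMI/FNN
  tau: 10
  m: 4
  units: per_second
stats:
  alpha: 0.05
  alpha_posthoc: 0.006
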