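# Demo pipeline configuration: small synthetic cohorts, full stage chain.
# Run with:  retclust run --config configs/demo.yaml --out scratch/demo_run
seed: 1
simulate:
  n_healthy: 45
  n_glaucoma: 12
  depth_range: [4.0, 14.0]
  vf_depth_scale: 1.8
  inl_ratio: 0.3
  vf_noise_sd: 1.0
match:
  age_window: 7.5
  se_window: 2.0
  min_subgroup: 3
cluster:
  k_max: 10
  criterion: 1.0
  feature_mode: participants
min_stratum: 3
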