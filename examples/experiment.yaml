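# Full default study: generate, fit the model battery, compare rankings.
seed: 1
out_dir: runs/demo
generate: {}          # DGPConfig overrides, e.g. n_proposals: 150
models:
  - outside_only
  - distance_proposal_fe
  - two_way_fe
  - novelty_covariates
  - random_slope
  - variance_model
ranking:
  k: 1
  quartiles: 4
# recovery: {reps: 20, model: two_way_fe}
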