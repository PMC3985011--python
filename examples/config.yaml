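# Demo pipeline configuration: simulate a default-size cohort
# (3 CNTL / 4 HF / 6 HHF, 40 secretome proteins) and run the pooled
# analysis end to end.
seed: 7
output_dir: out
generator:
  n_cntl: 3
  n_hf: 4
  n_hhf: 6
  n_proteins: 40
  noise_sd: 0.3
group_filter: pooled
per_group_runs: false
bma:
  occam_ratio: 20.0
  window_size: null       # defaults to min(8, n-3)
  retention_threshold: 0.5
congruence:
  magnitude_floor: 0.001
  size_ratio_cap: 10.0
  strict_sign: true
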