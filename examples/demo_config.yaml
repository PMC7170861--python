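# Demo end-to-end run: two simulated genotypes, filtering, metrics,
# summaries, and a rank-sum comparison of the directionality index.
out_dir: scratch/demo_out
axis: [1.0, 0.0]
simulate:
  defaults:
    dt: 0.75
    duration: 60.0
    speed_mean: 12.0
    speed_sd: 3.0
    persistence: 0.3
  groups:
    WT:   {bias: 0.5, n_cells: 60, seed: 101}
    DKO:  {bias: 0.0, n_cells: 60, seed: 102}
filter:
  min_path_length: 50.0
  static_displacement_threshold: 2.0
window:
  recording_span: [0.0, 60.0]
compare:
  metric: dmi
  method: rank_sum
  groups: [WT, DKO]
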