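# Bundled end-to-end demo: generates a synthetic cohort and runs every stage.
# Group proportions are enriched for severe anxiety (vs the default cohort)
# so all model contrasts are estimable at this small demo size.
out_dir: demo_out
seed: 7
log_level: INFO
synth:
  n_patients: 200
  group_props: [0.30, 0.50, 0.20]
  grid_shape: [48, 48, 48]
  voxel_size_mm: 1.0
  n_streamlines_per_side: 40
stats:
  bootstrap: 200
  alpha: 0.05
  q: 0.05
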