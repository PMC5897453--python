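# Desk-scale demo cohort: two myotube groups, three force maps each.
# Run:  myoelast run --config examples/demo.yaml --out run1 --seed 7
seed: 7
acquisition:
  grid_rows: 12
  grid_cols: 14
  scan_width_um: 11.0
  scan_height_um: 4.0
  samples_per_curve: 512
  noise_sd_nm: 0.3
cohort:
  groups:
    - label: WT-thin
      n_maps: 3
      mixture: [0.5, 557, 80, 1200, 150]
      diameter_mean_um: 3.5
      diameter_sd_um: 0.4
    - label: SOD1-thin
      n_maps: 3
      mixture: [0.5, 974, 107, 1839, 206]
      diameter_mean_um: 3.5
      diameter_sd_um: 0.4
stats:
  binning: fixed_width
  bin_width_Pa: 100
  alpha: 0.05
  comparison_plan:
    - [WT-thin, SOD1-thin]
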