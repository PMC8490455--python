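seed: 7
output_dir: runs/demo
reference_period: [1995, 1999]
analysis_years: [2001]
standard: ISO
climate:
  grid_shape: [4, 4]
  base_mean: 22.0
  noise_sd: 2.0
heatwaves:
  - start: "2001-07-10"
    duration: 10
    amplitude: 10.0
regions: {n_regions: 4, n_countries: 2}
economy: {n_regions: 4, n_countries: 2, trade_openness: 0.2}
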