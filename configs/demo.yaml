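alpha: 0.05
index_kind: NDVI
m_try: 4
n_components: 2
n_strata: 5
n_trees: 500
output_dir: demo_run
scenario:
  base_level: 0.45
  composites_per_year: 23
  dropout_prob: 0.05
  factor_effects:
  - - NLight
    - linear
    - -0.004
  field_length_scale: 6.0
  flow_link:
    id: linear
    scale: 6.0
  flow_noise_sigma: 0.0
  grid:
    cell_size: 250.0
    crs_label: albers_equal_area
    n_cols: 64
    n_rows: 64
    origin_x: 0.0
    origin_y: 16000.0
  n_flow_records: 262144
  n_years: 20
  noise_sigma: 0.02
  seasonal_amplitude: 0.08
  seed: 0
  slope_residual_sigma: 0.001
  start_year: 2000
  trend_per_year: 0.0024
seed: 0
sg_polyorder: 2
sg_window: 7
train_frac: 0.7
urban_threshold: 4000.0
vegetation_threshold: 0.2
write_rasters: true
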