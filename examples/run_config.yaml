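# Demo configuration for `zipquant run --config examples/run_config.yaml`.
# Any omitted section falls back to the package defaults; unknown keys are
# rejected before any stage runs.
seed: 1
outdir: zipquant_demo
stages:
  simulate: true
  scan: true
  pdi: true
  pla: true
  fractions: true
utr_sim:
  n_per_group: 20
  length_range: [300, 800]
  motif_rate_localized: 1.0
  motif_rate_control: 0.15
  region_plant: {length: 171, ga_fraction: 0.85}
cell_sim:
  image_size: 256
  cell_radius: 100
  nucleus_radius: 30
spot_sim:
  n_spots: 500
  bias_exponent: 2.0
pla_sim:
  n_dots: 10
  dot_amplitude: 100.0
  dot_region_split: 0.6
fraction_sim:
  true_ratio_per_gene: {RAB13: 3.0, NET1: 2.0, CTRL: 1.0}
compartments:
  band_fraction: 0.1
pla_params:
  k_sd: 3.0
  min_dot_area: 4
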