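# Full-pipeline configuration for `fluocube run --config ...`
# All seeds are explicit; rerunning the same file is bit-identical.
sim:
  n_bands: 25
  wl_min: 603.0
  wl_max: 870.0
  image_height: 64
  image_width: 64
  noise_sd: 0.01
  seed: 6
scenes_per_group: 2
n_spectra_per_group: 400
mask_band_wl: 673.0
mask_method: otsu
preprocess_methods: [smoothing, msc, snv]
fraction: 0.75
k_max: 10
trim: [0.5, 99.5]
alpha: 0.05
seed: 6
out_dir: scratch/yaml_run
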