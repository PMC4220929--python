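# Default CD3/DAB quantification profile.
# Values here mirror the package defaults; edit a copy to tune a new stain.
analysis_magnification: 20.0
mask_magnification: 1.25
nominal_magnification: 40.0
tile_size: 2048
min_keep: 0.01
blur_sigma: 2.0
fuzz: 0.10
min_region: 50
threshold:
  method: otsu3_entropy
  correction_factor: 1.3
  lower_bound: 0.5
  upper_bound: 1.0
  middle_class_to: foreground
  absolute_value: null
min_diameter: 8.0
max_diameter: 26.0
c_max: 1.5
tissue_smooth_sigma: 5.0
tissue_threshold: 0.03
tissue_min_diameter: 40.0
restrict_to_tissue: true
save_tiles: true
save_overlays: false
workers: 1
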