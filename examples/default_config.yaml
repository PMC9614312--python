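# Default pipeline configuration (every CLI flag overrides its key here).
# search_* null means tile-derived defaults: dy in [10%, 50%] of the shorter
# tile height, dx within +/-10% of the width.
blend:
  levels: 3
  theta: 0.5
  wavelet_family: haar
canny:
  bright_mask_quantile: null
  high_abs: 0.2
  high_percentile: 90.0
  kernel_size: 5
  low_abs: 0.08
  low_ratio: 0.4
  sigma: 1.0
  threshold_mode: absolute
downsample_factor: 1
quality_ceiling: 2.0
refine: true
search_dx: null
search_dy_max: null
search_dy_min: null
seed: 0
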