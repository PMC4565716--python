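# Feature catalog: the single source of truth for the 103-dimensional
# tumor descriptor (85 texture/fractal features + 18 SUV summaries).
# Order here fixes the order of every FeatureVector and features CSV.
version: 1
families:
  first_order:
    kind: texture
    features:
      - fo_mean
      - fo_median
      - fo_mode
      - fo_minimum
      - fo_maximum
      - fo_p5
      - fo_p10
      - fo_p25
      - fo_p75
      - fo_p90
      - fo_p95
      - fo_range
      - fo_iqr
      - fo_variance
      - fo_std
      - fo_cv
      - fo_skewness
      - fo_kurtosis
      - fo_energy
      - fo_entropy
      - fo_rms
      - fo_mean_abs_deviation
      - fo_median_abs_deviation
      - fo_uniformity
      - fo_trimmed_mean_10
      - fo_midrange
  glcm:
    kind: texture
    features:
      - glcm_energy
      - glcm_autocorrelation
      - glcm_cluster_prominence
      - glcm_cluster_shade
      - glcm_contrast
      - glcm_correlation
      - glcm_difference_entropy
      - glcm_difference_variance
      - glcm_dissimilarity
      - glcm_entropy
      - glcm_homogeneity
      - glcm_inverse_difference_moment
      - glcm_imc1
      - glcm_imc2
      - glcm_sum_average
      - glcm_sum_entropy
      - glcm_sum_variance
      - glcm_idmn
      - glcm_idn
      - glcm_max_probability
  glrlm:
    kind: texture
    features:
      - glrlm_short_run_emphasis
      - glrlm_long_run_emphasis
      - glrlm_low_gray_level_run_emphasis
      - glrlm_high_gray_level_run_emphasis
      - glrlm_short_run_low_gray_level_emphasis
      - glrlm_short_run_high_gray_level_emphasis
      - glrlm_long_run_low_gray_level_emphasis
      - glrlm_long_run_high_gray_level_emphasis
      - glrlm_gray_level_nonuniformity
      - glrlm_run_length_nonuniformity
      - glrlm_run_percentage
      - glrlm_gray_level_variance
      - glrlm_run_length_variance
  glszm:
    kind: texture
    features:
      - glszm_small_zone_emphasis
      - glszm_large_zone_emphasis
      - glszm_low_gray_level_zone_emphasis
      - glszm_high_gray_level_zone_emphasis
      - glszm_small_zone_low_gray_emphasis
      - glszm_small_zone_high_gray_emphasis
      - glszm_large_zone_low_gray_emphasis
      - glszm_large_zone_high_gray_emphasis
      - glszm_gray_level_nonuniformity
      - glszm_size_zone_nonuniformity
      - glszm_zone_percentage
      - glszm_gray_level_variance
      - glszm_zone_size_variance
  gldm:
    kind: texture
    features:
      - gldm_mean
      - gldm_entropy
      - gldm_variance
      - gldm_contrast
  ngtdm:
    kind: texture
    features:
      - ngtdm_coarseness
      - ngtdm_contrast
      - ngtdm_busyness
      - ngtdm_complexity
      - ngtdm_strength
  fractal:
    kind: texture
    features:
      - fractal_fd_mean
      - fractal_fd_std
      - fractal_hurst
      - fractal_lacunarity
  suv:
    kind: suv
    features:
      - suv_max
      - suv_min
      - suv_mean
      - suv_median
      - suv_std
      - suv_peak
      - suv_p5
      - suv_p10
      - suv_p25
      - suv_p75
      - suv_p90
      - suv_p95
      - suv_range
      - suv_iqr
      - suv_total
      - suv_max_mean_ratio
      - mtv_cc
      - tlg
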