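{
  "version": "1.0",
  "description": "LIFEx-compatible 56-feature radiomic catalog: 25 first-order, 26 second-order (7 GLCM + 11 GLZLM + 8 GLRLM), 5 shape.",
  "quantization": {"n_levels": 64, "bounds": "relative (ROI min..max, LIFEx rule)"},
  "first_order": [
    "CONVENTIONAL_min", "CONVENTIONAL_max", "CONVENTIONAL_range",
    "CONVENTIONAL_mean", "CONVENTIONAL_std", "CONVENTIONAL_variance",
    "CONVENTIONAL_CoV", "CONVENTIONAL_skewness", "CONVENTIONAL_kurtosis",
    "CONVENTIONAL_ExcessKurtosis", "CONVENTIONAL_Q1", "CONVENTIONAL_median",
    "CONVENTIONAL_Q3", "CONVENTIONAL_IQR", "CONVENTIONAL_P10",
    "CONVENTIONAL_P90", "CONVENTIONAL_HistogramMode", "CONVENTIONAL_sum",
    "CONVENTIONAL_RMS", "CONVENTIONAL_MAD", "CONVENTIONAL_RobustMAD",
    "CONVENTIONAL_Entropy_log2", "CONVENTIONAL_Entropy_log10",
    "CONVENTIONAL_Uniformity", "CONVENTIONAL_Energy"
  ],
  "glcm": [
    "GLCM_Homogeneity", "GLCM_Energy", "GLCM_Contrast", "GLCM_Correlation",
    "GLCM_Entropy_log10", "GLCM_Entropy_log2", "GLCM_Dissimilarity"
  ],
  "glzlm": [
    "GLZLM_SZE", "GLZLM_LZE", "GLZLM_LGZE", "GLZLM_HGZE", "GLZLM_SZLGE",
    "GLZLM_SZHGE", "GLZLM_LZLGE", "GLZLM_LZHGE", "GLZLM_GLNU", "GLZLM_ZLNU",
    "GLZLM_ZP"
  ],
  "glrlm": [
    "GLRLM_SRE", "GLRLM_LRE", "GLRLM_LGRE", "GLRLM_HGRE", "GLRLM_SRHGE",
    "GLRLM_GLNU", "GLRLM_RLNU", "GLRLM_RP"
  ],
  "shape": [
    "SHAPE_Volume_vx", "SHAPE_Volume_mL", "SHAPE_Surface_mm2",
    "SHAPE_Sphericity", "SHAPE_Compacity"
  ]
}
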