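{
  "description": "Published per-region summary statistics of the paired comparison between the conventional T2 TSE sequence and its DRB-reconstructed variant in 36 subjects: per side, mean volume under each sequence (mm3), mean per-subject volume difference (DRB - TSE, mm3), SD of that difference, and the Holm-corrected p-value. Used to calibrate the synthetic cohort generator; the p-values are kept only as qualitative anchors.",
  "n_subjects": 36,
  "units": "mm3",
  "columns": ["mean_tse", "mean_drb", "mean_diff", "sd_diff", "corrected_p"],
  "rows": {
    "Parasubiculum":           {"right": [63.9, 64.0, 0.2, 1.6, 1.0],      "left": [66.9, 65.9, -1.0, 2.1, 0.726]},
    "Presubiculum-Head":       {"right": [124.4, 123.5, -0.9, 4.0, 1.0],   "left": [128.6, 129.5, 0.9, 5.9, 1.0]},
    "Subiculum-Head":          {"right": [186.4, 185.8, -0.6, 4.2, 1.0],   "left": [188.4, 188.3, -0.04, 4.2, 0.958]},
    "CA1-Head":                {"right": [566.0, 569.9, 3.9, 9.6, 0.55],   "left": [556.8, 559.2, 2.4, 9.6, 1.0]},
    "CA2/3-Head":              {"right": [137.3, 136.9, -0.4, 3.7, 1.0],   "left": [130.0, 128.7, -1.3, 3.5, 0.871]},
    "CA4-Head":                {"right": [141.2, 139.7, -1.5, 2.9, 0.158], "left": [134.9, 134.6, -0.2, 3.9, 1.0]},
    "GC-ML-DG-head":           {"right": [174.2, 172.5, -1.7, 3.5, 0.234], "left": [166.8, 166.7, -0.1, 4.7, 1.0]},
    "molecular_layer_HP-head": {"right": [323.5, 324.6, 1.1, 10.3, 1.0],   "left": [341.0, 337.6, -3.4, 11.3, 1.0]},
    "HATA":                    {"right": [66.1, 65.4, -0.6, 1.9, 1.0],     "left": [67.4, 64.6, -2.8, 12.8, 1.0]},
    "Presubiculum-body":       {"right": [139.3, 140.2, 0.9, 3.9, 1.0],    "left": [157.2, 158.8, 1.5, 4.7, 1.0]},
    "Subiculum-body":          {"right": [232.9, 232.7, -0.3, 4.3, 1.0],   "left": [250.1, 249.3, -0.8, 6.0, 1.0]},
    "CA1-Body":                {"right": [133.2, 135.2, 2.0, 2.6, 0.003],  "left": [130.1, 128.9, -1.1, 4.3, 1.0]},
    "CA2/3-body":              {"right": [92.4, 91.5, -0.9, 4.0, 1.0],     "left": [89.2, 87.0, -2.2, 4.1, 0.126]},
    "CA4-body":                {"right": [116.1, 113.1, -3.0, 3.3, 0.0002],"left": [116.3, 114.8, -1.5, 3.5, 0.55]},
    "GC-ML-DG-body":           {"right": [129.6, 130.5, 0.9, 20.5, 1.0],   "left": [130.8, 130.2, -0.6, 4.5, 1.0]},
    "molecular_layer_HP-body": {"right": [250.0, 248.2, -1.8, 23.3, 1.0],  "left": [239.9, 238.2, -1.8, 6.9, 1.0]},
    "fimbria":                 {"right": [73.0, 74.3, 1.4, 3.4, 0.681],    "left": [72.6, 74.9, 2.3, 4.1, 0.079]},
    "Hippocampal_tail":        {"right": [564.5, 564.7, 0.2, 6.4, 1.0],    "left": [561.7, 563.1, 1.3, 6.4, 1.0]},
    "hippocampal-fissure":     {"right": [138.8, 138.5, -0.4, 4.3, 1.0],   "left": [135.6, 137.5, 1.9, 17.1, 1.0]},
    "Whole_hippocampal_body":  {"right": [1166.5, 1158.7, -7.8, 13.8, 0.012], "left": [1186.2, 1182.0, -4.2, 15.7, 0.491]},
    "Whole_hippocampal_head":  {"right": [1782.9, 1782.5, -0.4, 19.1, 0.897], "left": [1778.6, 1777.1, -1.5, 19.9, 1.0]},
    "Whole_hippocampus":       {"right": [3513.9, 3505.9, -8.0, 27.8, 0.487], "left": [3526.5, 3522.1, -4.3, 33.6, 1.0]}
  }
}
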