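{
  "description": "Published worked example: per-region right and left hippocampal subfield volumes (mm3) of a patient with right-sided hippocampal sclerosis, scanned with the DRB-reconstructed T2 TSE sequence, together with the right-minus-left difference column as printed in the source table. The printed difference was computed from unrounded volumes before rounding, so for some rows it differs by 0.1 mm3 from the difference of the rounded volumes; it is retained because it is the more faithful input for reproducing the published z-scores.",
  "sequence": "T2_TSE_DRB",
  "units": "mm3",
  "columns": ["right", "left", "printed_diff"],
  "rows": {
    "Parasubiculum":           [33.0, 53.7, -20.7],
    "Presubiculum-Head":       [70.6, 108.1, -37.6],
    "Subiculum-Head":          [101.7, 148.1, -46.4],
    "CA1-Head":                [251.1, 437.4, -186.3],
    "CA2/3-Head":              [62.8, 99.8, -37.0],
    "CA4-Head":                [53.4, 99.9, -46.5],
    "GC-ML-DG-head":           [67.3, 123.1, -55.8],
    "molecular_layer_HP-head": [151.9, 251.8, -99.9],
    "HATA":                    [44.7, 53.3, -8.6],
    "Presubiculum-body":       [73.2, 132.1, -58.9],
    "Subiculum-body":          [121.9, 216.7, -94.8],
    "CA1-Body":                [67.2, 130.3, -63.1],
    "CA2/3-body":              [39.2, 82.3, -43.1],
    "CA4-body":                [40.6, 103.4, -62.7],
    "GC-ML-DG-body":           [46.7, 117.4, -70.7],
    "molecular_layer_HP-body": [145.8, 239.4, -93.7],
    "fimbria":                 [24.4, 32.9, -8.5],
    "Hippocampal_tail":        [288.5, 486.2, -197.6],
    "hippocampal-fissure":     [101.1, 126.3, -25.2],
    "Whole_hippocampal_body":  [559.2, 1054.5, -495.3],
    "Whole_hippocampal_head":  [836.5, 1375.2, -538.8],
    "Whole_hippocampus":       [1684.2, 2915.9, -1231.8]
  }
}
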