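{
  "description": "Normative right-minus-left volume differences (mm3) of hippocampal subfields and combined labels, estimated in 20 healthy controls scanned with both a conventional T2 TSE sequence and a deep-learning-reconstructed (DRB) T2 TSE variant. mean/sd are the per-region mean and sample SD of the per-subject right-left difference.",
  "n_controls": 20,
  "units": "mm3",
  "rows": {
    "Parasubiculum":           {"T2_TSE_DRB": [-7.6, 13.8],  "T2_TSE": [-7.2, 13.8]},
    "Presubiculum-Head":       {"T2_TSE_DRB": [-6.3, 16.3],  "T2_TSE": [-5.9, 13.1]},
    "Subiculum-Head":          {"T2_TSE_DRB": [-2.5, 18.9],  "T2_TSE": [-2.6, 18.2]},
    "CA1-Head":                {"T2_TSE_DRB": [11.0, 36.8],  "T2_TSE": [9.3, 40.5]},
    "CA2/3-Head":              {"T2_TSE_DRB": [9.4, 17.7],   "T2_TSE": [7.8, 17.3]},
    "CA4-Head":                {"T2_TSE_DRB": [5.2, 14.0],   "T2_TSE": [7.4, 13.4]},
    "GC-ML-DG-head":           {"T2_TSE_DRB": [6.3, 18.6],   "T2_TSE": [9.0, 18.6]},
    "molecular_layer_HP-head": {"T2_TSE_DRB": [-2.1, 25.0],  "T2_TSE": [-4.7, 23.8]},
    "HATA":                    {"T2_TSE_DRB": [0.7, 8.1],    "T2_TSE": [0.5, 8.8]},
    "Presubiculum-body":       {"T2_TSE_DRB": [-19.0, 22.5], "T2_TSE": [-18.8, 20.0]},
    "Subiculum-body":          {"T2_TSE_DRB": [-13.5, 18.0], "T2_TSE": [-15.6, 14.2]},
    "CA1-Body":                {"T2_TSE_DRB": [9.1, 23.2],   "T2_TSE": [4.5, 22.6]},
    "CA2/3-body":              {"T2_TSE_DRB": [7.4, 16.5],   "T2_TSE": [5.5, 17.7]},
    "CA4-body":                {"T2_TSE_DRB": [-0.8, 11.8],  "T2_TSE": [-0.2, 12.3]},
    "GC-ML-DG-body":           {"T2_TSE_DRB": [-1.1, 14.9],  "T2_TSE": [-0.7, 16.0]},
    "molecular_layer_HP-body": {"T2_TSE_DRB": [7.4, 25.0],   "T2_TSE": [11.3, 23.9]},
    "fimbria":                 {"T2_TSE_DRB": [0.1, 17.0],   "T2_TSE": [0.1, 19.5]},
    "Hippocampal_tail":        {"T2_TSE_DRB": [0.7, 57.0],   "T2_TSE": [0.9, 56.0]},
    "hippocampal-fissure":     {"T2_TSE_DRB": [-3.0, 18.5],  "T2_TSE": [-3.6, 19.9]},
    "Whole_hippocampal_body":  {"T2_TSE_DRB": [-10.6, 74.5], "T2_TSE": [-13.8, 70.6]},
    "Whole_hippocampal_head":  {"T2_TSE_DRB": [13.9, 107.0], "T2_TSE": [13.5, 99.5]},
    "Whole_hippocampus":       {"T2_TSE_DRB": [4.0, 194.9],  "T2_TSE": [0.6, 181.9]}
  }
}
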