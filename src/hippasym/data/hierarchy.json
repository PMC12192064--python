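{
  "description": "Hippocampal subfield catalogue: the 19 subregions segmented by the FreeSurfer hippocampal-subfield pipeline, their grouping into the HEAD/BODY/TAIL/FISSURE merged labels, and the three combined labels obtained by summing member subregions. Aliases accept FreeSurfer v7 output spellings and common variants.",
  "subregions": [
    "Parasubiculum",
    "Presubiculum-Head",
    "Subiculum-Head",
    "CA1-Head",
    "CA2/3-Head",
    "CA4-Head",
    "GC-ML-DG-head",
    "molecular_layer_HP-head",
    "HATA",
    "Presubiculum-body",
    "Subiculum-body",
    "CA1-Body",
    "CA2/3-body",
    "CA4-body",
    "GC-ML-DG-body",
    "molecular_layer_HP-body",
    "fimbria",
    "Hippocampal_tail",
    "hippocampal-fissure"
  ],
  "merged_labels": {
    "HEAD": [
      "Parasubiculum", "Presubiculum-Head", "Subiculum-Head", "CA1-Head",
      "CA2/3-Head", "CA4-Head", "GC-ML-DG-head", "molecular_layer_HP-head",
      "HATA"
    ],
    "BODY": [
      "Presubiculum-body", "Subiculum-body", "CA1-Body", "CA2/3-body",
      "CA4-body", "GC-ML-DG-body", "molecular_layer_HP-body", "fimbria"
    ],
    "TAIL": ["Hippocampal_tail"],
    "FISSURE": ["hippocampal-fissure"]
  },
  "combined_labels": {
    "Whole_hippocampal_head": ["HEAD"],
    "Whole_hippocampal_body": ["BODY"],
    "Whole_hippocampus": ["HEAD", "BODY", "TAIL"]
  },
  "aliases": {
    "CA3-Head": "CA2/3-Head",
    "CA3-Body": "CA2/3-body",
    "CA23-Head": "CA2/3-Head",
    "CA23-Body": "CA2/3-body",
    "HP_tail": "Hippocampal_tail",
    "hippocampus-fissure": "hippocampal-fissure"
  }
}
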