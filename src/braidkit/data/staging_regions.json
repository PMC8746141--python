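{
  "regions": [
    {"name": "I", "labels": ["entorhinal"]},
    {"name": "II", "labels": ["hippocampus"]},
    {"name": "III", "labels": ["parahippocampal"]},
    {"name": "IV", "labels": ["rostralanteriorcingulate", "caudalanteriorcingulate"]},
    {"name": "V", "labels": ["cuneus", "pericalcarine", "lateraloccipital", "lingual"]}
  ]
}
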