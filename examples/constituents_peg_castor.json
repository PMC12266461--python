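{
  "_comment": "Illustrative constituent dictionary for a PEG castor oil product (synthetic example; real products need the manufacturer's raw-material list).",
  "adduct": "Na",
  "n_range": [0, 80],
  "bases": [
    {"name": "PEG", "formula": "H2O"},
    {"name": "glycerol-EO", "formula": "C3H8O3"}
  ]
}
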