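{
  "description": "Position-specific base frequencies of the vertebrate translation-initiation (Kozak) context, window -6..+4 anchored at the A of the start codon (offset 0). Frequencies follow the canonical vertebrate compilation around gccRccATGG; the ATG itself is fixed. Synthetic consensus-derived stand-in for a published species-specific matrix; replace via FeatureConfig.kozak to use one.",
  "neutral": 0.25,
  "positions": [
    {"offset": -6, "A": 0.23, "C": 0.35, "G": 0.23, "T": 0.19},
    {"offset": -5, "A": 0.26, "C": 0.35, "G": 0.21, "T": 0.18},
    {"offset": -4, "A": 0.25, "C": 0.26, "G": 0.25, "T": 0.24},
    {"offset": -3, "A": 0.61, "C": 0.02, "G": 0.36, "T": 0.01},
    {"offset": -2, "A": 0.27, "C": 0.49, "G": 0.13, "T": 0.11},
    {"offset": -1, "A": 0.15, "C": 0.55, "G": 0.21, "T": 0.09},
    {"offset": 0, "A": 1.0, "C": 0.0, "G": 0.0, "T": 0.0},
    {"offset": 1, "A": 0.0, "C": 0.0, "G": 0.0, "T": 1.0},
    {"offset": 2, "A": 0.0, "C": 0.0, "G": 1.0, "T": 0.0},
    {"offset": 3, "A": 0.23, "C": 0.16, "G": 0.46, "T": 0.15}
  ]
}
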