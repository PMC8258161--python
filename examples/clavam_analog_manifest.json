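{
  "name": "clavam_analog",
  "facts": {
    "n_metabolites": 19,
    "n_reactions": 18,
    "free_net": 5,
    "free_xch": 2,
    "species_counts": {
      "GLX": 4,
      "AGX": 3
    },
    "grid_counts_at_10pct": {
      "GLX": 286,
      "AGX": 66,
      "total": 18876
    },
    "synthetic_prices": true,
    "published_prices": {
      "GLX/12C": 0.36,
      "AGX/U-13C5": 3449.0
    },
    "amounts_config": {
      "medium_concentrations": {
        "GLX": 20.0,
        "AGX": 0.17
      },
      "dilution_rate": 0.03,
      "volume": 0.25,
      "residence_times": 5.0
    },
    "reference_mixture": {
      "GLX": [
        0.0,
        0.0,
        1.0,
        0.0
      ],
      "AGX": [
        0.0,
        1.0,
        0.0
      ]
    }
  }
}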