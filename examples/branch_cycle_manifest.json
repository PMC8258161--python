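{
  "name": "branch_cycle",
  "facts": {
    "n_metabolites": 9,
    "n_reactions": 8,
    "free_net": 3,
    "free_xch": 1,
    "singular_mixture": {
      "SA": [
        0.0,
        0.0,
        1.0
      ],
      "SB": [
        0.0,
        0.0,
        1.0
      ]
    },
    "informative_mixture": {
      "SA": [
        0.5,
        0.0,
        0.5
      ],
      "SB": [
        0.0,
        1.0,
        0.0
      ]
    },
    "informative_n_act": 3,
    "reference_mixture": {
      "SA": [
        0.0,
        1.0,
        0.0
      ],
      "SB": [
        1.0,
        0.0,
        0.0
      ]
    }
  }
}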