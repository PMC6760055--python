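{
  "rd_purity": {
    "response": "rd_purity",
    "scale": "uncoded-X, Z in mg/g, Y as fraction",
    "intercept": -0.12,
    "coefficients": {
      "X1": 3.382e-4,
      "X9": 1.824e-3,
      "X10": 1.869e-4,
      "Z5": 3.971e-3,
      "Z6": -8.607e-5
    },
    "p_values": {
      "X1": 0.0394,
      "X9": 1e-4,
      "X10": 1e-4,
      "Z5": 1e-4,
      "Z6": 1e-4
    },
    "r2": 0.9348,
    "adj_r2": 0.9223
  },
  "total_saponin_purity": {
    "response": "total_saponin_purity",
    "scale": "uncoded-X, Z in mg/g, Y as fraction",
    "intercept": 0.76,
    "coefficients": {
      "X1": 2.203e-3,
      "Z1": 0.0103,
      "Z2": 5.291e-3,
      "Z4": -0.0111
    },
    "p_values": {
      "X1": 0.0056,
      "Z1": 0.0143,
      "Z2": 0.0023,
      "Z4": 1e-4
    },
    "r2": 0.7460,
    "adj_r2": 0.7083
  }
}
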