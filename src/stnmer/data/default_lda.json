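{
  "weights": [
    1.2862667310393059,
    108.23021444986801
  ],
  "bias": -48.53428014353975,
  "class_order": [
    "out_stn",
    "in_stn"
  ],
  "training_meta": {
    "source": "synthetic",
    "generator_seeds": [
      1000,
      1001,
      1002,
      1003,
      1004,
      1005,
      1006,
      1007,
      1008,
      1009,
      1010,
      1011
    ],
    "n_sessions": 12,
    "n_in": 216,
    "n_out": 1260,
    "base_config": "SimConfig defaults",
    "trained_with": "stnmer 0.1.0"
  }
}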