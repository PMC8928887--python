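{
  "S": 20,
  "log10_mass_bounds": [-6.0, 2.0],
  "true_params": {"log10_a": -3.0, "ai": 0.5, "aj": 0.5, "b": 0.1},
  "removal_prob": 0.2,
  "seed": 2022
}
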