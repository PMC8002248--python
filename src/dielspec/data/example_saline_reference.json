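{
  "model": "debye",
  "description": "SYNTHETIC illustrative single-pole reference for a saline-like liquid at room temperature (water-like relaxation near 19 GHz plus ionic conduction). Not a literature model; supply your own concentration/temperature-specific model for real validations.",
  "eps_inf": 5.0,
  "sigma_s": 1.55,
  "poles": [
    {"delta_eps": 70.0, "tau_s": 8.5e-12}
  ]
}
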