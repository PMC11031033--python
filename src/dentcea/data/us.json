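{
  "market_name": "US",
  "currency": "USD",
  "conversion_rate": 1.0,
  "wtp_default": 50.0,
  "annual_discount_rate": 0.05,
  "time_horizon_months": 12,
  "reference_strategy": "CD",
  "strategies": [
    {"name": "CD", "cost_mean": 15.8, "cost_sd": null, "effect_mean": 1.9, "effect_sd": null, "role": "negative_control"},
    {"name": "BCD", "cost_mean": 48.3, "cost_sd": null, "effect_mean": 1.7, "effect_sd": null, "role": "candidate"},
    {"name": "HPD", "cost_mean": 115.9, "cost_sd": null, "effect_mean": 3.8, "effect_sd": null, "role": "candidate"},
    {"name": "CP10", "cost_mean": 400.1, "cost_sd": null, "effect_mean": 12.3, "effect_sd": null, "role": "positive_control"}
  ]
}
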