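{
  "market_name": "BR",
  "currency": "BRL",
  "conversion_rate": 5.42,
  "wtp_default": 50.0,
  "annual_discount_rate": 0.05,
  "time_horizon_months": 12,
  "reference_strategy": "CD",
  "strategies": [
    {"name": "CD", "cost_mean": 10.3, "cost_sd": null, "effect_mean": 1.9, "effect_sd": null, "role": "negative_control"},
    {"name": "BCD", "cost_mean": 10.6, "cost_sd": null, "effect_mean": 1.8, "effect_sd": null, "role": "candidate"},
    {"name": "HPD", "cost_mean": 24.9, "cost_sd": null, "effect_mean": 3.7, "effect_sd": null, "role": "candidate"},
    {"name": "CP10", "cost_mean": 136.3, "cost_sd": null, "effect_mean": 12.2, "effect_sd": null, "role": "positive_control"}
  ]
}
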