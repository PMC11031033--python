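"""End-to-end parameter recovery on fully synthetic inputs.

Generates trial arms and retailer price lists with known ground truth for four
strategies, rebuilds a market configuration from the synthetic raw data alone
(pooling + macro-costing), and checks that the estimated efficiency frontier
matches the frontier implied by the true parameters.
"""

from dentcea import (
    CostingRule,
    MarketConfig,
    Strategy,
    SynthSpec,
    annual_cost,
    average_price,
    frontier,
    generate_prices,
    generate_trials,
    pool_effectiveness,
)

# ground truth: (true delta-E, local unit price, one-off professional fee?)
truths = {
    "CD": (1.9, 4.652, False),
    "BCD": (1.8, 4.788, False),
    "HPD": (3.7, 11.247, False),
    "CP10": (12.2, 739.5, True),
}
kwargs = dict(market_name="synthetic-BR", reference_strategy="CD", conversion_rate=5.42)

true_cfg = MarketConfig(
    strategies=tuple(
        Strategy(n, cost_mean=(p / 5.42 if oneoff else 12 * p / 5.42), effect_mean=de)
        for n, (de, p, oneoff) in truths.items()
    ),
    **kwargs,
)

estimated = []
for i, (name, (de, price, oneoff)) in enumerate(truths.items()):
    spec = SynthSpec(
        name, true_delta_e=de, subject_sd=0.02, n_arms=4, n_per_arm=20,
        true_price=price, price_spread=0.01, n_retailers=3, seed=1000 + i,
    )
    pooled, _ = pool_effectiveness(generate_trials(spec))
    cost = annual_cost(
        average_price(generate_prices(spec)),
        CostingRule(one_off=True) if oneoff else CostingRule(units_per_month=1, months=12),
        true_cfg,
    )
    estimated.append(Strategy(name, cost_mean=cost, effect_mean=pooled))
    print(f"{name:>4}: true (cost {true_cfg.strategy(name).cost_mean:7.2f}, ΔE {de:5.2f})"
          f"  estimated (cost {cost:7.2f}, ΔE {pooled:5.2f})")

est_cfg = MarketConfig(strategies=tuple(estimated), **kwargs)
true_front = [s.name for s in frontier(true_cfg)]
est_front = [s.name for s in frontier(est_cfg)]
print(f"\nTrue frontier:      {true_front}")
print(f"Estimated frontier: {est_front}")
print(
    "\nWith effect separations of at least 5 subject-SDs the noisy synthetic\n"
    "pipeline recovers exactly the strategies a decision-maker should consider."
)
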