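"""Macro-costing: from retailer prices to annual USD strategy costs.

Averages retail tube prices, expands them over a 12-month one-tube-per-month
horizon, converts BRL to USD at 5.42, and sets a one-off professional
bleaching fee against income benchmarks.
"""

from dentcea import (
    CostingRule,
    PriceObservation,
    annual_cost,
    average_price,
    income_share,
    load_brazil_market,
)

config = load_brazil_market()

# three Brazilian marketplace listings for a conventional dentifrice (BRL/tube)
prices = [
    PriceObservation("marketplace-1", 4.39),
    PriceObservation("marketplace-2", 4.65),
    PriceObservation("marketplace-3", 4.91),
]
tube = average_price(prices)
annual = annual_cost(tube, CostingRule(units_per_month=1, months=12), config)
print(f"Average tube price: {tube:.2f} BRL")
print(f"Annual dentifrice cost (12 tubes, converted at 5.42 BRL/USD): {annual:.2f} USD")

fee = annual_cost(739.5, CostingRule(one_off=True), config)
print(f"\nOne-off professional at-home bleaching fee: 739.50 BRL = {fee:.1f} USD")
print(f"  = {income_share(fee, 223.6):.1f}% of a 223.6 USD monthly minimum wage")
print(f"  = {income_share(fee, 514.2):.1f}% of a 514.2 USD average monthly income")
print(
    "\nThese shares show the affordability gap: the supervised treatment costs a\n"
    "large fraction of a month's income, while a whitening dentifrice costs a\n"
    "few dollars a year more than the toothpaste the patient already buys."
)
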