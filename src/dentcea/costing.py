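"""Macro-costing of whitening strategies from retail prices and procedure fees.

Macro-costing values an intervention from aggregate unit prices — the retail
price of a tube of dentifrice times the number of tubes, or a single
professional-procedure fee — rather than itemised resource micro-costing.
Prices are collected in local currency (e.g. BRL), averaged across retailers,
expanded over the time horizon by a :class:`CostingRule`, optionally discounted,
and converted to USD by dividing by the market's local-per-USD conversion rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .parameters import ConfigError, MarketConfig

__all__ = [
    "PriceUnit",
    "PriceObservation",
    "CostingRule",
    "average_price",
    "annual_cost",
    "income_share",
]


class PriceUnit(str, Enum):
    TUBE = "tube"
    PROCEDURE = "procedure"


@dataclass(frozen=True)
class PriceObservation:
    """One retailer's unit price for a product, in local currency."""

    source: str
    unit_price: float
    unit: PriceUnit = PriceUnit.TUBE

    def __post_init__(self) -> None:
        if not (isinstance(self.unit_price, (int, float)) and math.isfinite(self.unit_price)):
            raise ConfigError(f"unit_price: must be a finite number, got {self.unit_price!r}")
        if self.unit_price <= 0:
            raise ConfigError(f"unit_price: must be > 0, got {self.unit_price}")
        object.__setattr__(self, "unit", PriceUnit(self.unit))


@dataclass(frozen=True)
class CostingRule:
    """How a unit price accrues over the time horizon.

    Recurring consumables (dentifrices) buy ``units_per_month`` units each month
    for ``months`` months; a one-off professional procedure is paid once at
    month 0, in which case ``units_per_month`` is ignored.
    """

    units_per_month: float = 1.0
    months: int = 12
    one_off: bool = False

    def __post_init__(self) -> None:
        if self.units_per_month < 0:
            raise ConfigError(f"units_per_month: must be >= 0, got {self.units_per_month}")
        if int(self.months) != self.months or self.months <= 0:
            raise ConfigError(f"months: must be a positive integer, got {self.months}")
        object.__setattr__(self, "months", int(self.months))


def average_price(observations: Sequence[PriceObservation] | Iterable[PriceObservation]) -> float:
    """Arithmetic mean of retailer unit prices, in local currency.

    All observations must share the same unit (all tubes, or all procedures).
    """
    obs = list(observations)
    if not obs:
        raise ConfigError("observations: need at least one price observation")
    units = {o.unit for o in obs}
    if len(units) > 1:
        raise ConfigError(f"observations: mixed units {sorted(u.value for u in units)}")
    return sum(o.unit_price for o in obs) / len(obs)


def annual_cost(
    price: float,
    rule: CostingRule,
    config: MarketConfig,
    *,
    discount: bool = False,
) -> float:
    """Total cost in USD of following ``rule`` at the given local-currency price.

    A recurring rule sums ``units_per_month * price`` over months ``1..months``.
    With ``discount=True`` each month's outlay is discounted at the monthly
    equivalent of the market's annual rate, ``(1 + r)**(1/12) - 1``; the default
    is undiscounted, which over a 12-month horizon differs immaterially and
    matches the packaged case studies. A one-off rule charges ``price`` once at
    month 0 with no discounting. The local total is converted to USD by dividing
    by ``config.conversion_rate`` (local units per USD).
    """
    if not (math.isfinite(price) and price > 0):
        raise ConfigError(f"price: must be a positive finite number, got {price!r}")
    if rule.one_off:
        local = price
    else:
        monthly = rule.units_per_month * price
        if discount and config.annual_discount_rate > 0:
            m = (1.0 + config.annual_discount_rate) ** (1.0 / 12.0) - 1.0
            local = sum(monthly / (1.0 + m) ** t for t in range(1, rule.months + 1))
        else:
            local = monthly * rule.months
    return local / config.conversion_rate


def income_share(cost: float, income: float) -> float:
    """Cost as a percentage of an income figure (same currency, any period).

    E.g. an at-home bleaching fee of 136.4 USD against a monthly minimum wage of
    223.6 USD is a 61.0% share.
    """
    if not (math.isfinite(income) and income > 0):
        raise ConfigError(f"income: must be a positive finite number, got {income!r}")
    return 100.0 * cost / income
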