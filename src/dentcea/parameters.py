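"""Domain types, validation, and I/O for strategy/market configuration.

A :class:`MarketConfig` bundles everything a cost-effectiveness run needs for one
market: the competing whitening strategies (each with a cost and an effectiveness
distribution, in USD and CIELAB ΔE*ab units respectively), the willingness-to-pay
default, the local-currency conversion rate, and the time horizon.

Costs are stored as floats in USD at full precision; rounding to 2 decimals is a
display concern only (see :func:`dentcea.cea.format_table`).
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ConfigError",
    "StrategyRole",
    "Strategy",
    "MarketConfig",
    "TrialArm",
    "SD_IMPUTATION_FACTOR",
    "load_market_config",
    "write_market_config",
    "load_strategies_csv",
    "write_strategies_csv",
    "load_trial_arms",
    "write_trial_arms",
]

#: Dispersion imputed when a strategy's SD is not given: sd = 0.2 x mean.
#: The probabilistic analysis needs dispersion; when a source table prints only
#: point values this documented, overridable coefficient of variation is used.
SD_IMPUTATION_FACTOR = 0.2


class ConfigError(ValueError):
    """A configuration value violates an invariant; the message names the field."""


class StrategyRole(str, Enum):
    CANDIDATE = "candidate"
    NEGATIVE_CONTROL = "negative_control"
    POSITIVE_CONTROL = "positive_control"


def _require_finite(value: float, field_name: str, *, minimum: float | None = None) -> float:
    try:
        value = float(value)
    except (TypeError, ValueError):
        raise ConfigError(f"{field_name}: expected a number, got {value!r}") from None
    if not math.isfinite(value):
        raise ConfigError(f"{field_name}: must be finite, got {value!r}")
    if minimum is not None and value < minimum:
        raise ConfigError(f"{field_name}: must be >= {minimum}, got {value}")
    return value


@dataclass(frozen=True)
class Strategy:
    """One treatment alternative in one market.

    Parameters
    ----------
    name
        Short label, e.g. ``"CD"`` (conventional dentifrice, negative control),
        ``"BCD"`` (blue covarine dentifrice), ``"HPD"`` (hydrogen peroxide
        dentifrice) or ``"CP10"`` (10% carbamide peroxide at-home bleaching).
    cost_mean, cost_sd
        Annual treatment cost in USD (mean and SD). ``cost_sd == 0`` makes the
        strategy deterministic in the probabilistic analysis.
    effect_mean, effect_sd
        Bleaching effectiveness as CIELAB ΔE*ab color change (mean and SD).
    role
        Whether the strategy is a candidate or a negative/positive control.
    """

    name: str
    cost_mean: float
    effect_mean: float
    cost_sd: float = 0.0
    effect_sd: float = 0.0
    role: StrategyRole = StrategyRole.CANDIDATE

    def __post_init__(self) -> None:
        if not isinstance(self.name, str) or not self.name:
            raise ConfigError(f"name: must be a non-empty string, got {self.name!r}")
        object.__setattr__(self, "cost_mean", _require_finite(self.cost_mean, f"{self.name}.cost_mean", minimum=0.0))
        object.__setattr__(self, "cost_sd", _require_finite(self.cost_sd, f"{self.name}.cost_sd", minimum=0.0))
        object.__setattr__(self, "effect_mean", _require_finite(self.effect_mean, f"{self.name}.effect_mean"))
        object.__setattr__(self, "effect_sd", _require_finite(self.effect_sd, f"{self.name}.effect_sd", minimum=0.0))
        object.__setattr__(self, "role", StrategyRole(self.role))


def _impute_sd(mean: float, sd: float | None, field_name: str) -> float:
    if sd is None:
        imputed = SD_IMPUTATION_FACTOR * abs(mean)
        warnings.warn(
            f"{field_name} not given; imputing sd = {SD_IMPUTATION_FACTOR} x mean = {imputed:.4g}",
            UserWarning,
            stacklevel=4,
        )
        return imputed
    return sd


@dataclass(frozen=True)
class MarketConfig:
    """A full strategy set for one market, ready for incremental analysis and PSA."""

    market_name: str
    strategies: tuple[Strategy, ...]
    reference_strategy: str
    currency: str = "USD"
    conversion_rate: float = 1.0  # local currency units per USD
    wtp_default: float = 50.0  # USD per unit of DeltaE*ab
    annual_discount_rate: float = 0.05
    time_horizon_months: int = 12

    def __post_init__(self) -> None:
        object.__setattr__(self, "strategies", tuple(self.strategies))
        if len(self.strategies) < 2:
            raise ConfigError(f"strategies: need at least 2, got {len(self.strategies)}")
        names = [s.name for s in self.strategies]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ConfigError(f"strategies: duplicate strategy name(s) {sorted(dupes)}")
        if self.reference_strategy not in names:
            raise ConfigError(
                f"reference_strategy: {self.reference_strategy!r} is not one of {names}"
            )
        object.__setattr__(
            self, "conversion_rate", _require_finite(self.conversion_rate, "conversion_rate")
        )
        if self.conversion_rate <= 0:
            raise ConfigError(f"conversion_rate: must be > 0, got {self.conversion_rate}")
        object.__setattr__(self, "wtp_default", _require_finite(self.wtp_default, "wtp_default", minimum=0.0))
        object.__setattr__(
            self,
            "annual_discount_rate",
            _require_finite(self.annual_discount_rate, "annual_discount_rate", minimum=0.0),
        )
        if int(self.time_horizon_months) != self.time_horizon_months or self.time_horizon_months <= 0:
            raise ConfigError(
                f"time_horizon_months: must be a positive integer, got {self.time_horizon_months}"
            )
        object.__setattr__(self, "time_horizon_months", int(self.time_horizon_months))

    def strategy(self, name: str) -> Strategy:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def strategy_names(self) -> list[str]:
        return [s.name for s in self.strategies]


@dataclass(frozen=True)
class TrialArm:
    """One clinical-trial arm: per-arm mean ΔE*ab, optional SD, and sample size."""

    study_id: str
    product: str
    strategy_name: str
    delta_e_mean: float
    n: int
    delta_e_sd: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta_e_mean", _require_finite(self.delta_e_mean, "delta_e_mean"))
        if self.delta_e_sd is not None:
            object.__setattr__(
                self, "delta_e_sd", _require_finite(self.delta_e_sd, "delta_e_sd", minimum=0.0)
            )
        if int(self.n) != self.n or self.n < 1:
            raise ConfigError(f"n: must be a positive integer, got {self.n}")
        object.__setattr__(self, "n", int(self.n))


# ---------------------------------------------------------------------------
# JSON config dialect
# ---------------------------------------------------------------------------

def _strategy_from_dict(d: dict) -> Strategy:
    for key in ("name", "cost_mean", "effect_mean"):
        if key not in d:
            raise ConfigError(f"strategy entry missing required field {key!r}: {d!r}")
    name = d["name"]
    cost_mean = _require_finite(d["cost_mean"], f"{name}.cost_mean", minimum=0.0)
    effect_mean = _require_finite(d["effect_mean"], f"{name}.effect_mean")
    cost_sd = d.get("cost_sd")
    effect_sd = d.get("effect_sd")
    return Strategy(
        name=name,
        cost_mean=cost_mean,
        effect_mean=effect_mean,
        cost_sd=_impute_sd(cost_mean, cost_sd, f"{name}.cost_sd"),
        effect_sd=_impute_sd(effect_mean, effect_sd, f"{name}.effect_sd"),
        role=StrategyRole(d.get("role", "candidate")),
    )


def load_market_config(path: str | Path) -> MarketConfig:
    """Read a market configuration from the JSON dialect.

    The file is a JSON object with market-level fields and a ``"strategies"``
    array; see ``dentcea/data/brazil.json`` for the canonical shape. A strategy
    whose ``cost_sd``/``effect_sd`` is absent or ``null`` gets the documented
    default ``sd = 0.2 x mean`` with a warning.

    Raises
    ------
    ConfigError
        On a missing field, duplicate strategy name, non-positive conversion
        rate, or any other invariant violation; the message names the field.
    """
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config root: expected a JSON object, got {type(raw).__name__}")
    for key in ("market_name", "strategies", "reference_strategy"):
        if key not in raw:
            raise ConfigError(f"config missing required field {key!r}")
    strategies = tuple(_strategy_from_dict(d) for d in raw["strategies"])
    return MarketConfig(
        market_name=raw["market_name"],
        strategies=strategies,
        reference_strategy=raw["reference_strategy"],
        currency=raw.get("currency", "USD"),
        conversion_rate=raw.get("conversion_rate", 1.0),
        wtp_default=raw.get("wtp_default", 50.0),
        annual_discount_rate=raw.get("annual_discount_rate", 0.05),
        time_horizon_months=raw.get("time_horizon_months", 12),
    )


def write_market_config(config: MarketConfig, path: str | Path) -> None:
    """Write ``config`` as JSON so that reloading it reproduces ``config`` exactly."""
    doc = {
        "market_name": config.market_name,
        "currency": config.currency,
        "conversion_rate": config.conversion_rate,
        "wtp_default": config.wtp_default,
        "annual_discount_rate": config.annual_discount_rate,
        "time_horizon_months": config.time_horizon_months,
        "reference_strategy": config.reference_strategy,
        "strategies": [
            {
                "name": s.name,
                "cost_mean": s.cost_mean,
                "cost_sd": s.cost_sd,
                "effect_mean": s.effect_mean,
                "effect_sd": s.effect_sd,
                "role": s.role.value,
            }
            for s in config.strategies
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

_STRATEGY_COLUMNS = ["name", "cost_mean", "cost_sd", "effect_mean", "effect_sd", "role"]
_TRIAL_COLUMNS = ["study_id", "product", "strategy_name", "delta_e_mean", "delta_e_sd", "n"]


def load_strategies_csv(path: str | Path) -> tuple[Strategy, ...]:
    """Read strategies from CSV with header ``name,cost_mean,cost_sd,effect_mean,effect_sd,role``.

    Empty SD cells are imputed as in :func:`load_market_config`.
    """
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != _STRATEGY_COLUMNS:
            raise ConfigError(
                f"strategies CSV header: expected {','.join(_STRATEGY_COLUMNS)}, got {reader.fieldnames}"
            )
        for row in reader:
            d = {k: (v if v not in ("", None) else None) for k, v in row.items()}
            out.append(_strategy_from_dict({k: v for k, v in d.items() if v is not None}))
    return tuple(out)


def write_strategies_csv(strategies: Iterable[Strategy], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_STRATEGY_COLUMNS)
        for s in strategies:
            writer.writerow([s.name, repr(s.cost_mean), repr(s.cost_sd), repr(s.effect_mean), repr(s.effect_sd), s.role.value])


def load_trial_arms(path: str | Path) -> list[TrialArm]:
    """Read trial-arm records from CSV with header
    ``study_id,product,strategy_name,delta_e_mean,delta_e_sd,n``.

    An empty ``delta_e_sd`` cell means the source trial did not report a
    dispersion for that arm.
    """
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != _TRIAL_COLUMNS:
            raise ConfigError(
                f"trial CSV header: expected {','.join(_TRIAL_COLUMNS)}, got {reader.fieldnames}"
            )
        for row in reader:
            sd = row["delta_e_sd"]
            out.append(
                TrialArm(
                    study_id=row["study_id"],
                    product=row["product"],
                    strategy_name=row["strategy_name"],
                    delta_e_mean=float(row["delta_e_mean"]),
                    delta_e_sd=float(sd) if sd not in ("", None) else None,
                    n=int(row["n"]),
                )
            )
    if not out:
        raise ConfigError("trial CSV: no arm records found")
    return out


def write_trial_arms(arms: Sequence[TrialArm], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TRIAL_COLUMNS)
        for a in arms:
            writer.writerow(
                [
                    a.study_id,
                    a.product,
                    a.strategy_name,
                    repr(a.delta_e_mean),
                    "" if a.delta_e_sd is None else repr(a.delta_e_sd),
                    a.n,
                ]
            )
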