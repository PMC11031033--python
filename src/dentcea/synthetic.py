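"""Synthetic trial arms and retailer price lists with known ground truth.

The generator emulates the two kinds of raw input the analysis consumes: small
randomized-trial arms reporting a per-arm mean ΔE*ab with its SD and sample
size (per-subject color change drawn normal around a known true mean), and
short retailer price lists (lognormal spread around a known true price, so
prices stay positive). Because the truths are known, pooling, costing, and the
full incremental analysis can be tested end-to-end for parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .costing import PriceObservation, PriceUnit
from .parameters import ConfigError, TrialArm, write_trial_arms

__all__ = ["SynthSpec", "generate_trials", "generate_prices", "write_price_csv"]


@dataclass(frozen=True)
class SynthSpec:
    """Ground truth for one synthetic strategy.

    ``true_delta_e``/``subject_sd`` parameterise per-subject color change;
    ``n_arms`` trials of ``n_per_arm`` subjects are simulated. ``true_price``
    is the median retail price and ``price_spread`` the lognormal sigma of the
    ``n_retailers`` observed prices.
    """

    strategy_name: str
    true_delta_e: float
    subject_sd: float
    n_arms: int = 4
    n_per_arm: int = 20
    true_price: float = 5.0
    price_spread: float = 0.1
    n_retailers: int = 3
    seed: int = 20240205

    def __post_init__(self) -> None:
        if self.subject_sd < 0:
            raise ConfigError(f"subject_sd: must be >= 0, got {self.subject_sd}")
        if self.n_arms < 1:
            raise ConfigError(f"n_arms: must be >= 1, got {self.n_arms}")
        if self.n_per_arm < 2:
            raise ConfigError(f"n_per_arm: must be >= 2, got {self.n_per_arm}")
        if not (math.isfinite(self.true_price) and self.true_price > 0):
            raise ConfigError(f"true_price: must be > 0, got {self.true_price}")
        if self.price_spread < 0:
            raise ConfigError(f"price_spread: must be >= 0, got {self.price_spread}")
        if self.n_retailers < 1:
            raise ConfigError(f"n_retailers: must be >= 1, got {self.n_retailers}")


def generate_trials(spec: SynthSpec) -> list[TrialArm]:
    """Simulate ``n_arms`` trial arms of per-subject normal ΔE*ab measurements.

    Each arm records the sample mean, sample SD (ddof=1) and n of ``n_per_arm``
    draws from Normal(true_delta_e, subject_sd). With ``subject_sd == 0`` every
    arm mean equals the truth exactly. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    arms = []
    for i in range(spec.n_arms):
        if spec.subject_sd == 0.0:
            arm_mean, arm_sd = spec.true_delta_e, 0.0
        else:
            subjects = rng.normal(spec.true_delta_e, spec.subject_sd, size=spec.n_per_arm)
            arm_mean, arm_sd = float(subjects.mean()), float(subjects.std(ddof=1))
        arms.append(
            TrialArm(
                study_id=f"synth-{spec.strategy_name}-{i + 1}",
                product=f"{spec.strategy_name} (synthetic)",
                strategy_name=spec.strategy_name,
                delta_e_mean=arm_mean,
                delta_e_sd=arm_sd,
                n=spec.n_per_arm,
            )
        )
    return arms


def generate_prices(spec: SynthSpec, unit: PriceUnit = PriceUnit.TUBE) -> list[PriceObservation]:
    """Simulate ``n_retailers`` lognormal prices with median ``true_price``.

    Prices are ``true_price * exp(price_spread * Z)`` with standard-normal Z,
    so the median is the true price and ``price_spread`` is the log-scale
    sigma. Deterministic for a fixed seed (offset from the trial stream so
    trials and prices are independent).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    z = rng.standard_normal(spec.n_retailers)
    prices = spec.true_price * np.exp(spec.price_spread * z)
    return [
        PriceObservation(source=f"synth-retailer-{i + 1}", unit_price=float(p), unit=unit)
        for i, p in enumerate(prices)
    ]


def write_price_csv(observations: list[PriceObservation], path: str | Path, currency: str = "USD") -> None:
    """Write prices in the CSV dialect ``source,unit_price,currency,unit``."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "unit_price", "currency", "unit"])
        for o in observations:
            writer.writerow([o.source, repr(o.unit_price), currency, o.unit.value])
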