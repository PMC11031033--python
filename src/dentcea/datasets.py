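"""Packaged case-study fixtures: Brazilian and US whitening markets.

Both markets compare four strategies over a 12-month horizon: a conventional
dentifrice (CD, negative control), a blue covarine dentifrice (BCD), a hydrogen
peroxide dentifrice (HPD), and supervised at-home bleaching with 10% carbamide
peroxide (CP10, positive control), with a default willingness to pay of 50 USD
per ΔE*ab unit. Costs are annual USD (one tube per month for the dentifrices;
a one-off professional fee for CP10, converted at 5.42 BRL per USD for Brazil).
Effectiveness is the pooled ΔE*ab used for each strategy in the model. The
source tables print point values only, so loading the fixtures imputes the
documented default dispersion (sd = 0.2 x mean) for the probabilistic analysis.

``load_included_trials`` returns the underlying randomized-clinical-trial arm
records (per-arm ΔE*ab mean and sample size; arm SDs were not reported).
"""

from __future__ import annotations

import warnings
from importlib import resources

from .parameters import MarketConfig, TrialArm, load_market_config, load_trial_arms

__all__ = ["load_brazil_market", "load_us_market", "load_included_trials", "fixture_path"]


def fixture_path(name: str):
    """Filesystem path of a packaged fixture (``brazil.json``, ``us.json``, ``trials.csv``)."""
    return resources.files("dentcea.data").joinpath(name)


def _load_market(name: str, quiet: bool) -> MarketConfig:
    with resources.as_file(fixture_path(name)) as path:
        if quiet:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                return load_market_config(path)
        return load_market_config(path)


def load_brazil_market(*, quiet: bool = True) -> MarketConfig:
    """The Brazilian-market strategy set (costs converted at 5.42 BRL/USD).

    ``quiet=False`` surfaces the SD-imputation warnings.
    """
    return _load_market("brazil.json", quiet)


def load_us_market(*, quiet: bool = True) -> MarketConfig:
    """The US-market strategy set."""
    return _load_market("us.json", quiet)


def load_included_trials() -> list[TrialArm]:
    """Arm records of the randomized clinical trials behind the case studies."""
    with resources.as_file(fixture_path("trials.csv")) as path:
        return load_trial_arms(path)
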