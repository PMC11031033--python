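import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dentcea import MarketConfig, Strategy, load_brazil_market, load_us_market

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def brazil():
    return load_brazil_market()


@pytest.fixture(scope="session")
def us():
    return load_us_market()


def random_config(rng: np.random.Generator, n_min: int = 2, n_max: int = 6) -> MarketConfig:
    """A random strategy set with continuous (hence a.s. tie-free) parameters."""
    n = int(rng.integers(n_min, n_max + 1))
    strategies = [
        Strategy(
            name=f"S{i}",
            cost_mean=float(rng.uniform(1.0, 500.0)),
            effect_mean=float(rng.uniform(0.0, 15.0)),
        )
        for i in range(n)
    ]
    return MarketConfig(market_name="synth", strategies=tuple(strategies), reference_strategy="S0")


def frontier_by_envelope(strategies) -> set[str]:
    """Brute-force frontier membership: winners of the upper NMB envelope.

    Evaluates the NMB argmax (ties to lower cost, then name) at w = 0, at the
    midpoint between every pair of consecutive pairwise crossing points, and
    beyond the last crossing, so any strategy optimal on a non-empty open
    interval of willingness-to-pay values is found. Independent of the
    dominance/ladder algorithm.
    """
    strategies = list(strategies)
    crossings = []
    for i, a in enumerate(strategies):
        for b in strategies[i + 1 :]:
            de = b.effect_mean - a.effect_mean
            if de != 0.0:
                w = (b.cost_mean - a.cost_mean) / de
                if w > 0:
                    crossings.append(w)
    pts = sorted(set([0.0] + crossings))
    evals = [0.0]
    evals += [(lo + hi) / 2.0 for lo, hi in zip(pts, pts[1:])]
    evals.append(pts[-1] + 1.0)

    winners = set()
    for w in evals:
        best = min(
            strategies,
            key=lambda s: (-(s.effect_mean * w - s.cost_mean), s.cost_mean, s.name),
        )
        winners.add(best.name)
    return winners
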