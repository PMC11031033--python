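"""Probabilistic sensitivity analysis by Monte Carlo simulation.

Parameter uncertainty is propagated by drawing, for every strategy and every
iteration of a hypothetical cohort, a cost from a gamma distribution and an
effectiveness from a normal distribution, each moment-matched to the strategy's
(mean, SD). Gamma keeps sampled costs non-negative, the convention for cost
parameters in PSA; normal effectiveness allows a color change to regress below
zero. A zero SD collapses the distribution to a point mass, so a fully
deterministic configuration reproduces the deterministic analysis exactly.

From the draws the module computes cost-effectiveness acceptability curves
(CEACs) — the probability, at each willingness-to-pay value on a grid, that a
strategy has the maximal sampled net monetary benefit — plus per-strategy PSA
means and a long-format scatter export for cost-effectiveness planes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .parameters import ConfigError, MarketConfig

__all__ = [
    "DEFAULT_WTP_GRID",
    "CeacCurve",
    "sample_psa",
    "ceac",
    "psa_summary",
    "scatter_export",
]

#: Default willingness-to-pay grid: 0..100 USD per ΔE*ab unit in steps of 1.
DEFAULT_WTP_GRID = np.arange(0.0, 101.0, 1.0)

#: Columns of the long-format draw table.
DRAW_COLUMNS = ["iteration", "strategy", "cost", "effectiveness"]


@dataclass(frozen=True)
class CeacCurve:
    """Per-strategy probability of being the optimal choice across a WTP grid.

    ``prob_optimal`` has one row per grid point and one column per strategy;
    at every grid point the probabilities partition the iterations and sum to 1.
    """

    wtp_grid: np.ndarray
    prob_optimal: pd.DataFrame

    def probability(self, strategy: str, wtp: float) -> float:
        """Probability that ``strategy`` is optimal at the grid point ``wtp``."""
        idx = np.flatnonzero(np.isclose(self.wtp_grid, wtp))
        if idx.size == 0:
            raise KeyError(f"wtp {wtp} is not on the grid")
        return float(self.prob_optimal.iloc[idx[0]][strategy])

    def to_long(self) -> pd.DataFrame:
        """CSV-ready long format with columns ``wtp,strategy,probability``."""
        df = self.prob_optimal.copy()
        df.insert(0, "wtp", self.wtp_grid)
        return df.melt(id_vars="wtp", var_name="strategy", value_name="probability")


def _draw_costs(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    if sd == 0.0:
        return np.full(n, mean)
    if mean == 0.0:
        raise ConfigError("cost_mean: gamma sampling needs mean > 0 when cost_sd > 0")
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, size=n)


def _draw_effects(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    if sd == 0.0:
        return np.full(n, mean)
    return rng.normal(mean, sd, size=n)


def sample_psa(config: MarketConfig, n_iter: int, seed: int) -> pd.DataFrame:
    """Draw ``n_iter`` Monte Carlo (cost, effectiveness) pairs per strategy.

    Returns a long-format DataFrame with columns
    ``iteration, strategy, cost, effectiveness``; the same seed always yields
    the identical draw set.
    """
    if n_iter < 1:
        raise ConfigError(f"n_iter: must be >= 1, got {n_iter}")
    rng = np.random.default_rng(seed)
    frames = []
    for s in config.strategies:
        costs = _draw_costs(rng, s.cost_mean, s.cost_sd, n_iter)
        effects = _draw_effects(rng, s.effect_mean, s.effect_sd, n_iter)
        frames.append(
            pd.DataFrame(
                {
                    "iteration": np.arange(n_iter),
                    "strategy": s.name,
                    "cost": costs,
                    "effectiveness": effects,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _pivot_draws(draws: pd.DataFrame, order: Sequence[str] | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(cost, effectiveness) wide tables, iterations x strategies."""
    costs = draws.pivot(index="iteration", columns="strategy", values="cost")
    effects = draws.pivot(index="iteration", columns="strategy", values="effectiveness")
    if costs.isna().any().any():
        raise ConfigError("draws: strategies have mismatched iteration counts")
    if order is not None:
        costs, effects = costs[list(order)], effects[list(order)]
    return costs, effects


def ceac(draws: pd.DataFrame, wtp_grid: Sequence[float] | np.ndarray = DEFAULT_WTP_GRID) -> CeacCurve:
    """Cost-effectiveness acceptability curves over a willingness-to-pay grid.

    At each grid point ``w`` a strategy's probability is the fraction of
    iterations in which its sampled NMB ``effectiveness * w - cost`` is
    maximal, ties going to the strategy with the lower sampled cost.
    """
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    strategies = list(pd.unique(draws["strategy"]))
    if len(strategies) < 2:
        raise ConfigError("draws: CEAC needs at least 2 strategies")
    costs, effects = _pivot_draws(draws, order=strategies)
    cost_arr = costs.to_numpy()
    effect_arr = effects.to_numpy()
    n_iter = cost_arr.shape[0]

    probs = np.empty((wtp_grid.size, len(strategies)))
    cost_rank = np.argsort(cost_arr, axis=1, kind="stable")  # tie-break template
    for gi, w in enumerate(wtp_grid):
        nmb = effect_arr * w - cost_arr
        # among NMB-maximal strategies pick the one with the lowest cost
        best = nmb.max(axis=1, keepdims=True)
        is_best = nmb == best
        # order candidate columns by ascending cost, take the first that is best
        winner = np.empty(n_iter, dtype=np.intp)
        taken = np.zeros(n_iter, dtype=bool)
        for k in range(len(strategies)):
            col = cost_rank[:, k]
            hit = ~taken & is_best[np.arange(n_iter), col]
            winner[hit] = col[hit]
            taken |= hit
        probs[gi] = np.bincount(winner, minlength=len(strategies)) / n_iter
    return CeacCurve(
        wtp_grid=wtp_grid,
        prob_optimal=pd.DataFrame(probs, columns=strategies),
    )


def psa_summary(draws: pd.DataFrame, wtp: float) -> pd.DataFrame:
    """Per-strategy Monte Carlo means: cost, effectiveness, and NMB at ``wtp``.

    By linearity of expectation the mean NMB equals
    ``mean effectiveness * wtp - mean cost``.
    """
    if draws.empty:
        raise ConfigError("draws: empty")
    order = list(pd.unique(draws["strategy"]))
    g = draws.groupby("strategy", sort=False)[["cost", "effectiveness"]].mean().loc[order]
    g["nmb"] = g["effectiveness"] * wtp - g["cost"]
    g.columns = ["mean_cost", "mean_effectiveness", "mean_nmb"]
    return g


def scatter_export(draws: pd.DataFrame, path: str | Path | None = None) -> pd.DataFrame:
    """Long-format ``strategy,cost,effectiveness`` table for CE-plane scatterplots.

    One row per draw (n_iter x n_strategies rows). When ``path`` is given the
    table is also written as CSV with values preserved to at least 10
    significant digits.
    """
    if draws.empty:
        raise ConfigError("draws: empty")
    table = draws[["strategy", "cost", "effectiveness"]].reset_index(drop=True)
    if path is not None:
        table.to_csv(path, index=False, float_format="%.12g")
    return table
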