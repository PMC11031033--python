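"""Deterministic incremental cost-effectiveness analysis.

Strategies are ordered from least to most costly, strictly dominated options
(another strategy costs no more and whitens strictly better, or costs strictly
less and whitens no worse) are flagged, and extended dominance removes frontier
candidates whose incremental cost-effectiveness ratio (ICER) against the
previous frontier member exceeds that of the next member — so ICERs strictly
increase along the surviving efficiency frontier. Each table row carries the
ICER against the previous less-costly frontier member (the row-wise convention
of published CEA tables), the net monetary benefit NMB = effectiveness x WTP -
cost at the chosen willingness-to-pay, and the percentage NMB gain over the
reference strategy. The frontier ICERs are exactly the willingness-to-pay
thresholds at which the optimal strategy switches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import pandas as pd

from .parameters import ConfigError, MarketConfig, Strategy

__all__ = [
    "DominanceStatus",
    "IncrementalRow",
    "nmb",
    "icer",
    "incremental_analysis",
    "frontier",
    "optimal_strategy",
    "wtp_switch_points",
    "rows_to_dataframe",
    "format_table",
    "write_table_csv",
    "rows_to_json",
]

#: Marker printed for an ICER with zero incremental effectiveness.
UNDEFINED_ICER_MARKER = "dominated-or-equal"


class DominanceStatus(str, Enum):
    NOT_DOMINATED = "not_dominated"
    DOMINATED = "dominated"
    EXTENDED_DOMINATED = "extended_dominated"


@dataclass(frozen=True)
class IncrementalRow:
    """One line of an incremental cost-effectiveness table.

    ``incr_cost``/``incr_effect``/``icer`` are measured against the previous
    less-costly frontier strategy and are ``None`` on the least costly row.
    ``icer`` is also ``None`` when the incremental effectiveness is zero (the
    ratio is undefined; tables print a dominated-or-equal marker instead).
    """

    strategy: str
    cost: float
    effectiveness: float
    incr_cost: float | None
    incr_effect: float | None
    icer: float | None
    nmb: float
    nmb_gain_pct: float | None
    status: DominanceStatus
    comparator: str | None

    @property
    def icer_undefined(self) -> bool:
        return self.incr_effect is not None and self.incr_effect == 0.0


def nmb(strategy: Strategy, wtp: float) -> float:
    """Net monetary benefit: effectiveness x WTP - cost, in USD."""
    if wtp < 0:
        raise ConfigError(f"wtp: must be >= 0, got {wtp}")
    return strategy.effect_mean * wtp - strategy.cost_mean


def icer(lower: Strategy, higher: Strategy) -> float | None:
    """Incremental cost-effectiveness ratio of ``higher`` against ``lower``.

    (cost_higher - cost_lower) / (effect_higher - effect_lower), in USD per
    ΔE*ab unit. Returns ``None`` (undefined, not an exception) when the
    effectiveness difference is zero.
    """
    if lower.name == higher.name:
        raise ConfigError("icer: strategies must be distinct")
    d_effect = higher.effect_mean - lower.effect_mean
    if d_effect == 0.0:
        return None
    return (higher.cost_mean - lower.cost_mean) / d_effect


def _sorted_by_cost(strategies: Sequence[Strategy]) -> list[Strategy]:
    return sorted(strategies, key=lambda s: (s.cost_mean, s.effect_mean, s.name))


def _strictly_dominated(s: Strategy, others: Sequence[Strategy]) -> bool:
    for t in others:
        if t.name == s.name:
            continue
        if t.cost_mean <= s.cost_mean and t.effect_mean > s.effect_mean:
            return True
        if t.cost_mean < s.cost_mean and t.effect_mean >= s.effect_mean:
            return True
    return False


def _classify(strategies: Sequence[Strategy]) -> dict[str, DominanceStatus]:
    """Strict dominance, then the ICER ladder for extended dominance."""
    ordered = _sorted_by_cost(strategies)
    status = {}
    candidates = []
    for s in ordered:
        if _strictly_dominated(s, ordered):
            status[s.name] = DominanceStatus.DOMINATED
        else:
            status[s.name] = DominanceStatus.NOT_DOMINATED
            candidates.append(s)

    # Duplicate (cost, effect) points are interchangeable; keep the first on
    # the ladder so consecutive candidates always differ in effectiveness.
    ladder: list[Strategy] = []
    for s in candidates:
        if ladder and s.cost_mean == ladder[-1].cost_mean and s.effect_mean == ladder[-1].effect_mean:
            continue
        ladder.append(s)

    changed = True
    while changed:
        changed = False
        i = 1
        while i < len(ladder) - 1:
            r_prev = icer(ladder[i - 1], ladder[i])
            r_next = icer(ladder[i], ladder[i + 1])
            assert r_prev is not None and r_next is not None
            if r_prev >= r_next:
                status[ladder[i].name] = DominanceStatus.EXTENDED_DOMINATED
                del ladder[i]
                changed = True
            else:
                i += 1
    return status


def frontier(config: MarketConfig) -> list[Strategy]:
    """The efficiency frontier: non-dominated strategies in ascending cost order."""
    status = _classify(config.strategies)
    return [
        s
        for s in _sorted_by_cost(config.strategies)
        if status[s.name] is DominanceStatus.NOT_DOMINATED
    ]


def incremental_analysis(
    config: MarketConfig,
    wtp: float | None = None,
    *,
    icer_mode: str = "ladder",
) -> list[IncrementalRow]:
    """Build the incremental cost-effectiveness table for a market.

    Parameters
    ----------
    config
        The market's strategy set; at least two strategies with unique names.
    wtp
        Willingness to pay in USD per ΔE*ab unit; defaults to the market's
        ``wtp_default``.
    icer_mode
        ``"ladder"`` (default) computes each row's incremental quantities
        against the previous less-costly frontier strategy, as published CEA
        tables do; ``"reference"`` computes every row against the market's
        reference strategy.

    Returns rows sorted by ascending cost, each with dominance status, ICER,
    NMB at ``wtp`` and the percentage NMB gain over the reference strategy
    (with ``|NMB_ref|`` in the denominator so the sign stays interpretable for
    a negative reference NMB).
    """
    if wtp is None:
        wtp = config.wtp_default
    if icer_mode not in ("ladder", "reference"):
        raise ConfigError(f"icer_mode: expected 'ladder' or 'reference', got {icer_mode!r}")
    ordered = _sorted_by_cost(config.strategies)
    status = _classify(config.strategies)
    reference = config.strategy(config.reference_strategy)
    nmb_ref = nmb(reference, wtp)

    rows = []
    last_frontier: Strategy | None = None
    for s in ordered:
        if icer_mode == "reference":
            comparator = None if s.name == reference.name else reference
        else:
            comparator = last_frontier
        if comparator is None:
            incr_cost = incr_effect = row_icer = None
        else:
            incr_cost = s.cost_mean - comparator.cost_mean
            incr_effect = s.effect_mean - comparator.effect_mean
            row_icer = icer(comparator, s)
        nmb_s = nmb(s, wtp)
        gain = None if nmb_ref == 0.0 else 100.0 * (nmb_s - nmb_ref) / abs(nmb_ref)
        rows.append(
            IncrementalRow(
                strategy=s.name,
                cost=s.cost_mean,
                effectiveness=s.effect_mean,
                incr_cost=incr_cost,
                incr_effect=incr_effect,
                icer=row_icer,
                nmb=nmb_s,
                nmb_gain_pct=gain,
                status=status[s.name],
                comparator=None if comparator is None else comparator.name,
            )
        )
        if status[s.name] is DominanceStatus.NOT_DOMINATED:
            if not (
                last_frontier is not None
                and s.cost_mean == last_frontier.cost_mean
                and s.effect_mean == last_frontier.effect_mean
            ):
                last_frontier = s
    return rows


def optimal_strategy(config: MarketConfig, wtp: float) -> str:
    """Name of the strategy with maximal NMB at ``wtp``; ties go to lower cost."""
    return min(
        config.strategies, key=lambda s: (-nmb(s, wtp), s.cost_mean, s.name)
    ).name


def wtp_switch_points(config: MarketConfig) -> list[tuple[float, str]]:
    """Breakpoints of the piecewise-linear upper NMB envelope.

    Returns ``(threshold, strategy)`` pairs: strictly above each WTP threshold
    the named strategy becomes optimal, and it stays optimal until the next
    threshold. Below the first threshold the least costly frontier strategy is
    optimal. The thresholds equal the frontier ICERs and strictly increase; a
    single-member frontier yields an empty list.
    """
    front = frontier(config)
    # collapse duplicate (cost, effect) points, as in the ladder
    dedup: list[Strategy] = []
    for s in front:
        if dedup and s.cost_mean == dedup[-1].cost_mean and s.effect_mean == dedup[-1].effect_mean:
            continue
        dedup.append(s)
    out = []
    for prev, cur in zip(dedup, dedup[1:]):
        threshold = icer(prev, cur)
        assert threshold is not None  # frontier members differ in effectiveness
        out.append((threshold, cur.name))
    return out


# ---------------------------------------------------------------------------
# Table export
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "Dominance",
    "Strategy",
    "Cost USD",
    "Incremental Cost",
    "Effectiveness",
    "Incremental Effectiveness",
    "ICER",
    "NMB",
    "%NMB Gain",
]

_STATUS_LABEL = {
    DominanceStatus.NOT_DOMINATED: "Not dominated",
    DominanceStatus.DOMINATED: "Dominated",
    DominanceStatus.EXTENDED_DOMINATED: "Extended dominated",
}


def rows_to_dataframe(rows: Sequence[IncrementalRow]) -> pd.DataFrame:
    """Full-precision DataFrame with the standard incremental-table columns."""
    return pd.DataFrame(
        {
            "Dominance": [_STATUS_LABEL[r.status] for r in rows],
            "Strategy": [r.strategy for r in rows],
            "Cost USD": [r.cost for r in rows],
            "Incremental Cost": [r.incr_cost for r in rows],
            "Effectiveness": [r.effectiveness for r in rows],
            "Incremental Effectiveness": [r.incr_effect for r in rows],
            "ICER": [r.icer for r in rows],
            "NMB": [r.nmb for r in rows],
            "%NMB Gain": [r.nmb_gain_pct for r in rows],
        },
        columns=_TABLE_COLUMNS,
    )


def _fmt(value: float | None, decimals: int, *, undefined: str = "-") -> str:
    if value is None:
        return undefined
    return f"{value:.{decimals}f}"


def format_table(rows: Sequence[IncrementalRow], *, decimals: int = 1) -> str:
    """Aligned text rendering of the incremental table (display rounding only)."""
    body = []
    for r in rows:
        icer_cell = UNDEFINED_ICER_MARKER if r.icer_undefined else _fmt(r.icer, decimals)
        gain = "-" if r.nmb_gain_pct is None else f"{r.nmb_gain_pct:.1f}%"
        body.append(
            [
                _STATUS_LABEL[r.status],
                r.strategy,
                _fmt(r.cost, decimals),
                _fmt(r.incr_cost, decimals),
                _fmt(r.effectiveness, decimals),
                _fmt(r.incr_effect, decimals),
                icer_cell,
                _fmt(r.nmb, decimals),
                gain,
            ]
        )
    widths = [
        max(len(_TABLE_COLUMNS[j]), *(len(row[j]) for row in body)) for j in range(len(_TABLE_COLUMNS))
    ]
    lines = [
        "  ".join(h.ljust(w) for h, w in zip(_TABLE_COLUMNS, widths)),
        "  ".join("-" * w for w in widths),
    ]
    for row in body:
        lines.append("  ".join(cell.ljust(w) for cell, w in zip(row, widths)))
    return "\n".join(lines)


def write_table_csv(rows: Sequence[IncrementalRow], path: str | Path) -> None:
    df = rows_to_dataframe(rows).copy()
    undef = [r.icer_undefined for r in rows]
    df["ICER"] = [
        UNDEFINED_ICER_MARKER if u else v for u, v in zip(undef, df["ICER"])
    ]
    df.to_csv(path, index=False)


def rows_to_json(rows: Sequence[IncrementalRow]) -> str:
    return json.dumps(
        [
            {
                "strategy": r.strategy,
                "cost": r.cost,
                "effectiveness": r.effectiveness,
                "incr_cost": r.incr_cost,
                "incr_effect": r.incr_effect,
                "icer": UNDEFINED_ICER_MARKER if r.icer_undefined else r.icer,
                "nmb": r.nmb,
                "nmb_gain_pct": r.nmb_gain_pct,
                "status": r.status.value,
                "comparator": r.comparator,
            }
            for r in rows
        ],
        indent=2,
    )
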