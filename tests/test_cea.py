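import json

import numpy as np
import pytest

from dentcea import (
    ConfigError,
    DominanceStatus,
    MarketConfig,
    Strategy,
    format_table,
    frontier,
    icer,
    incremental_analysis,
    nmb,
    optimal_strategy,
    rows_to_dataframe,
    rows_to_json,
    wtp_switch_points,
    write_table_csv,
)
from conftest import frontier_by_envelope, random_config


def _cfg(*triples, reference=None):
    strategies = tuple(Strategy(name, cost, effect) for name, cost, effect in triples)
    return MarketConfig(
        market_name="T",
        strategies=strategies,
        reference_strategy=reference or strategies[0].name,
    )


def _row(rows, name):
    return next(r for r in rows if r.strategy == name)


class TestNmb:
    def test_break_even(self):
        assert nmb(Strategy("A", 100.0, 2.0), 50.0) == 0.0

    def test_zero_wtp_is_minus_cost(self):
        assert nmb(Strategy("A", 10.3, 1.9), 0.0) == -10.3

    def test_conventional_dentifrice_brazil(self, brazil):
        # 1.9 x 50 - 10.3; the published table prints 84.2 from unrounded inputs
        assert nmb(brazil.strategy("CD"), 50.0) == pytest.approx(84.7)

    def test_negative_wtp_rejected(self):
        with pytest.raises(ConfigError, match="wtp"):
            nmb(Strategy("A", 1.0, 1.0), -1.0)


class TestIcer:
    def test_bleaching_vs_peroxide_dentifrice_brazil(self, brazil):
        value = icer(brazil.strategy("HPD"), brazil.strategy("CP10"))
        assert value == pytest.approx((136.3 - 24.9) / (12.2 - 3.7))
        assert round(value, 1) == 13.1

    def test_equal_effectiveness_is_undefined_not_an_exception(self):
        assert icer(Strategy("A", 1.0, 2.0), Strategy("B", 3.0, 2.0)) is None

    def test_negative_icer_for_costlier_less_effective_option(self, us):
        value = icer(us.strategy("CD"), us.strategy("BCD"))
        assert value < 0  # magnitude depends on printed rounding; sign is robust

    def test_identical_strategy_rejected(self):
        s = Strategy("A", 1.0, 2.0)
        with pytest.raises(ConfigError, match="distinct"):
            icer(s, s)


class TestIncrementalAnalysis:
    def test_brazil_dominance_and_ladder(self, brazil):
        rows = incremental_analysis(brazil, wtp=50.0)
        assert [r.strategy for r in rows] == ["CD", "BCD", "HPD", "CP10"]
        assert _row(rows, "BCD").status is DominanceStatus.DOMINATED
        assert _row(rows, "CD").status is DominanceStatus.NOT_DOMINATED
        assert _row(rows, "CP10").status is DominanceStatus.NOT_DOMINATED
        cp10 = _row(rows, "CP10")
        assert cp10.comparator == "HPD"
        assert cp10.incr_effect == pytest.approx(8.5)
        assert round(cp10.icer, 1) == 13.1
        assert cp10.nmb == max(r.nmb for r in rows)

    def test_us_dominance_and_ladder(self, us):
        rows = incremental_analysis(us, wtp=50.0)
        assert _row(rows, "BCD").status is DominanceStatus.DOMINATED
        assert _row(rows, "HPD").status is DominanceStatus.EXTENDED_DOMINATED
        cp10 = _row(rows, "CP10")
        assert cp10.comparator == "CD"  # HPD fell off the frontier
        assert cp10.incr_cost == pytest.approx(384.3)
        assert cp10.incr_effect == pytest.approx(10.4)
        hpd = _row(rows, "HPD")
        assert hpd.incr_cost == pytest.approx(100.1)
        assert cp10.nmb == max(r.nmb for r in rows)
        assert {s.name for s in frontier(us)} == {"CD", "CP10"}

    def test_least_costly_row_has_no_incremental_columns(self, brazil):
        first = incremental_analysis(brazil)[0]
        assert first.incr_cost is None and first.incr_effect is None and first.icer is None

    def test_equal_cost_tie_dominates_less_effective(self):
        rows = incremental_analysis(_cfg(("A", 10.0, 2.0), ("B", 10.0, 1.0)))
        assert _row(rows, "B").status is DominanceStatus.DOMINATED
        assert _row(rows, "A").status is DominanceStatus.NOT_DOMINATED

    def test_invariant_to_input_strategy_order(self, brazil):
        shuffled = MarketConfig(
            market_name=brazil.market_name,
            strategies=tuple(reversed(brazil.strategies)),
            reference_strategy=brazil.reference_strategy,
            conversion_rate=brazil.conversion_rate,
            wtp_default=brazil.wtp_default,
        )
        assert incremental_analysis(shuffled) == incremental_analysis(brazil)

    def test_reference_mode_compares_everything_to_reference(self, us):
        rows = incremental_analysis(us, icer_mode="reference")
        for r in rows:
            if r.strategy == "CD":
                assert r.comparator is None
            else:
                assert r.comparator == "CD"
        assert _row(rows, "CP10").icer == pytest.approx((400.1 - 15.8) / (12.3 - 1.9))

    def test_nmb_gain_uses_reference_magnitude(self, brazil):
        rows = incremental_analysis(brazil, wtp=50.0)
        ref_nmb = _row(rows, "CD").nmb
        assert _row(rows, "CD").nmb_gain_pct == 0.0
        assert _row(rows, "CP10").nmb_gain_pct == pytest.approx(
            100 * (_row(rows, "CP10").nmb - ref_nmb) / abs(ref_nmb)
        )
        assert _row(rows, "BCD").nmb_gain_pct < 0

    def test_duplicate_names_rejected(self):
        with pytest.raises(ConfigError, match="duplicate"):
            _cfg(("A", 1.0, 1.0), ("A", 2.0, 2.0))


class TestOptimalStrategy:
    def test_brazil_wtp_50_picks_bleaching(self, brazil):
        assert optimal_strategy(brazil, 50.0) == "CP10"

    def test_zero_wtp_picks_cheapest(self, brazil):
        assert optimal_strategy(brazil, 0.0) == "CD"

    def test_matches_brute_force_argmax_on_grid(self, brazil, us):
        for cfg in (brazil, us):
            for w in np.arange(0.0, 100.5, 0.5):
                expected = min(
                    cfg.strategies,
                    key=lambda s: (-(s.effect_mean * w - s.cost_mean), s.cost_mean, s.name),
                ).name
                assert optimal_strategy(cfg, float(w)) == expected


class TestSwitchPoints:
    def test_brazil_final_switch_is_max_frontier_icer(self, brazil):
        points = wtp_switch_points(brazil)
        assert [name for _, name in points] == ["HPD", "CP10"]
        assert points[-1][0] == pytest.approx((136.3 - 24.9) / (12.2 - 3.7))

    def test_us_switch_is_icer_vs_cd(self, us):
        points = wtp_switch_points(us)
        assert [name for _, name in points] == ["CP10"]
        assert points[0][0] == pytest.approx((400.1 - 15.8) / (12.3 - 1.9))

    def test_single_frontier_strategy_has_no_switches(self):
        # B dominated: costlier and less effective
        assert wtp_switch_points(_cfg(("A", 10.0, 5.0), ("B", 20.0, 1.0))) == []

    @pytest.mark.parametrize("fixture_name", ["brazil", "us"])
    def test_agrees_with_dense_grid_scan(self, fixture_name, brazil, us):
        # oracle: scan the NMB argmax over wtp steps of 0.01 and read off where
        # the winner changes; thresholds must bracket the claimed switch points
        cfg = {"brazil": brazil, "us": us}[fixture_name]
        points = wtp_switch_points(cfg)
        grid = np.arange(0.0, 60.0, 0.01)
        winners = [optimal_strategy(cfg, float(w)) for w in grid]
        scan = [
            (float(grid[i]), winners[i])
            for i in range(1, len(grid))
            if winners[i] != winners[i - 1]
        ]
        assert len(scan) == len(points)
        for (w_scan, name_scan), (w_exact, name_exact) in zip(scan, points):
            assert name_scan == name_exact
            assert w_exact < w_scan <= w_exact + 0.011

    def test_between_switch_points_optimum_is_constant(self, brazil):
        points = wtp_switch_points(brazil)
        edges = [0.0] + [w for w, _ in points] + [points[-1][0] + 20.0]
        for lo, hi in zip(edges, edges[1:]):
            mids = np.linspace(lo + 1e-6, hi - 1e-6, 5)
            assert len({optimal_strategy(brazil, float(w)) for w in mids}) == 1


class TestFrontierOracle:
    def test_ladder_matches_envelope_on_random_configs(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            cfg = random_config(rng)
            ladder = {s.name for s in frontier(cfg)}
            assert ladder == frontier_by_envelope(cfg.strategies)

    def test_frontier_icers_strictly_increase(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            cfg = random_config(rng)
            front = frontier(cfg)
            icers = [icer(a, b) for a, b in zip(front, front[1:])]
            assert all(r is not None for r in icers)
            assert all(a < b for a, b in zip(icers, icers[1:]))

    def test_dominated_strategy_never_wins_at_positive_wtp(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            cfg = random_config(rng)
            rows = incremental_analysis(cfg)
            losers = {r.strategy for r in rows if r.status is not DominanceStatus.NOT_DOMINATED}
            for w in np.linspace(0.5, 200.0, 40):
                assert optimal_strategy(cfg, float(w)) not in losers


class TestExports:
    def test_dataframe_has_published_column_set(self, brazil):
        df = rows_to_dataframe(incremental_analysis(brazil))
        assert list(df.columns) == [
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
        assert len(df) == 4

    def test_text_table_renders_all_strategies(self, brazil):
        text = format_table(incremental_analysis(brazil))
        for name in brazil.strategy_names:
            assert name in text
        assert "Dominated" in text

    def test_undefined_icer_rendered_symbolically(self):
        cfg = _cfg(("A", 10.0, 2.0), ("B", 15.0, 2.0))
        text = format_table(incremental_analysis(cfg))
        assert "dominated-or-equal" in text
        assert "inf" not in text

    def test_csv_and_json_round_trip(self, brazil, tmp_path):
        rows = incremental_analysis(brazil)
        out = tmp_path / "table.csv"
        write_table_csv(rows, out)
        header = out.read_text().splitlines()[0]
        assert header.split(",") == [
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
        parsed = json.loads(rows_to_json(rows))
        assert [p["strategy"] for p in parsed] == ["CD", "BCD", "HPD", "CP10"]
        assert parsed[3]["nmb"] == pytest.approx(12.2 * 50 - 136.3)
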