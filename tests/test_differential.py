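"""Performance deciles, pooled lagged networks and differential thresholding."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import flownet as fn
from flownet.differential import GROUP_HIGH, GROUP_LOW, GROUP_MID

from conftest import make_records
from test_metrics import net_from_edges


def perf_frame(values, site="DH", start="2015-01-01"):
    dates = pd.date_range(start, periods=len(values), freq="D")
    return pd.DataFrame(
        {"date": dates, "site": site, "performance_pct": values, "arrivals": 100}
    )


class TestPerformanceGroups:
    def test_578_days_split_57_464_57(self):
        rng = np.random.default_rng(0)
        groups = fn.performance_groups(perf_frame(rng.uniform(40, 100, 578)), "DH")
        assert (groups.n_high, groups.n_mid, groups.n_low) == (57, 464, 57)

    def test_ten_distinct_days(self):
        groups = fn.performance_groups(perf_frame(np.arange(10, dtype=float) * 5 + 40), "DH")
        assert (groups.n_high, groups.n_mid, groups.n_low) == (1, 8, 1)
        assert groups.days(GROUP_HIGH) == {pd.Timestamp("2015-01-10")}
        assert groups.days(GROUP_LOW) == {pd.Timestamp("2015-01-01")}

    def test_constant_series_tie_broken_by_date(self):
        groups = fn.performance_groups(perf_frame(np.full(20, 80.0)), "DH")
        assert (groups.n_high, groups.n_mid, groups.n_low) == (2, 16, 2)
        assert groups.days(GROUP_HIGH).isdisjoint(groups.days(GROUP_LOW))
        # deterministic across calls
        again = fn.performance_groups(perf_frame(np.full(20, 80.0)), "DH")
        assert groups.labels.equals(again.labels)

    def test_fewer_than_ten_days_rejected(self):
        with pytest.raises(fn.UsageError):
            fn.performance_groups(perf_frame([80] * 9), "DH")


FIVE_DAY_RECORDS = [
    # day 1: 2 transfers A->B; day 2: B->C; day 3: A->B; day 4: C->EXIT x2; day 5: A->C
    ("p1", "2015-01-01T08:00", "DH", "A", "B"),
    ("p2", "2015-01-01T09:00", "DH", "A", "B"),
    ("p3", "2015-01-02T08:00", "DH", "B", "C"),
    ("p4", "2015-01-03T08:00", "DH", "A", "B"),
    ("p5", "2015-01-04T08:00", "DH", "C", "EXIT"),
    ("p6", "2015-01-04T09:00", "DH", "C", "EXIT"),
    ("p7", "2015-01-05T08:00", "DH", "A", "C"),
]


class TestPooledNetwork:
    def test_lag_zero_single_day(self):
        records = make_records(FIVE_DAY_RECORDS)
        net = fn.pooled_network(records, {pd.Timestamp("2015-01-01")}, "DH", lag=0)
        assert net.total_count == 2
        assert sum(net.edges().values()) == pytest.approx(1.0)

    def test_lag_one_shifts_contributing_days(self):
        records = make_records(FIVE_DAY_RECORDS)
        days = {pd.Timestamp("2015-01-04"), pd.Timestamp("2015-01-05")}
        net = fn.pooled_network(records, days, "DH", lag=1)
        # pools days 3 and 4: one A->B and two C->EXIT
        assert net.to_count().edges() == {("A", "B"): 1, ("C", "EXIT"): 2}

    def test_lagged_day_before_start_dropped(self):
        records = make_records(FIVE_DAY_RECORDS)
        net = fn.pooled_network(records, {pd.Timestamp("2015-01-01")}, "DH", lag=3)
        assert net.n_edges == 0

    def test_negative_lag_rejected(self):
        with pytest.raises(fn.UsageError):
            fn.pooled_network(make_records(FIVE_DAY_RECORDS), set(), "DH", lag=-1)


class TestDifferentialNetwork:
    def test_identical_networks_give_zero(self):
        net = net_from_edges([("A", "B", 0.6), ("B", "C", 0.4)], weight_mode="proportion")
        dn = fn.differential_network(net, net)
        assert dn.sd == 0 and dn.retained.empty
        assert all(v == 0 for v in dn.diffs.values())

    def test_single_large_difference_retained(self):
        small = {(f"W{i}", f"V{i}"): 0.01 for i in range(10)}
        best_edges = [("A", "B", 0.3 + 0.05)] + [(u, v, w + 0.005) for (u, v), w in small.items()]
        worst_edges = [("A", "B", 0.05)] + [(u, v, w - 0.005) for (u, v), w in small.items()]
        best = net_from_edges(best_edges, weight_mode="proportion")
        worst = net_from_edges(worst_edges, weight_mode="proportion")
        dn = fn.differential_network(best, worst)
        assert len(dn.retained) == 1
        row = dn.retained.iloc[0]
        assert (row.source, row.target, row.direction) == ("A", "B", "better")
        assert abs(row.sd_units) > 2

    def test_count_mode_rejected(self):
        count = net_from_edges([("A", "B", 3)])
        with pytest.raises(fn.UsageError):
            fn.differential_network(count, count)

    def test_antisymmetry(self, sim60):
        groups = fn.performance_groups(sim60.performance, "PRUH")
        best = fn.pooled_network(sim60.records, groups.days(GROUP_HIGH), "PRUH", lag=1)
        worst = fn.pooled_network(sim60.records, groups.days(GROUP_LOW), "PRUH", lag=1)
        fwd = fn.differential_network(best, worst)
        rev = fn.differential_network(worst, best)
        assert rev.sd == pytest.approx(fwd.sd)
        assert len(rev.retained) == len(fwd.retained)
        for edge, d in fwd.diffs.items():
            assert rev.diffs[edge] == pytest.approx(-d)

    def test_diffs_sum_to_zero_over_union(self, sim60):
        groups = fn.performance_groups(sim60.performance, "PRUH")
        dn = fn.lagged_differential(sim60.records, groups, lag=0)
        assert sum(dn.diffs.values()) == pytest.approx(0.0, abs=1e-9)


class TestLagSweep:
    def test_max_lag_zero_matches_same_day_differential(self, sim60):
        sweep = fn.lag_sweep(sim60.records, sim60.performance, "PRUH", max_lag=0)
        groups = fn.performance_groups(sim60.performance, "PRUH")
        dn = fn.lagged_differential(sim60.records, groups, lag=0)
        assert len(sweep) == 1
        assert sweep.loc[0, "sd"] == pytest.approx(dn.sd)

    def test_uncoupled_simulation_has_flat_profile(self):
        """Without planted coupling no lag should dominate the SD profile."""
        params = fn.default_params("pruh", n_days=59)
        params.coupling = []
        result = fn.simulate(params, seed=5)
        sweep = fn.lag_sweep(result.records, result.performance, "PRUH", max_lag=7)
        assert sweep["sd"].max() < 2.5 * sweep["sd"].median()
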