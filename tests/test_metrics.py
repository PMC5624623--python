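"""Node statistics: degree roles, variability score (with brute-force oracle),
path centrality."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flownet as fn
from flownet.base import EXIT
from flownet.metrics import ROLE_BALANCED, ROLE_IN, ROLE_OUT
from flownet.network import FlowNetwork
from flownet.paths import PatientPath

from conftest import make_records


def net_from_edges(edges, weight_mode="count", window="w"):
    g = nx.DiGraph()
    total = 0
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
        total += w if weight_mode == "count" else 0
    return FlowNetwork(graph=g, window=window, weight_mode=weight_mode, total_count=total)


def brute_force_variability(weights):
    """Independent oracle: evaluate the observed/extremal deviations directly.

    The extremal configuration is built explicitly (k-1 edges of weight 1,
    one edge with the remaining total) and both deviations are computed with
    the same sum-of-absolute-deviations formula.
    """
    w = list(weights)
    k = len(w)
    mean = sum(w) / k

    def deviation(vec):
        m = sum(vec) / len(vec)
        return sum(abs(x - m) for x in vec) / m

    obs = deviation(w)
    if obs == 0:
        return 0.0
    extreme = [1] * (k - 1) + [sum(w) - (k - 1)]
    return obs / deviation(extreme)


class TestDegreeDifference:
    def test_hand_counts(self):
        net = net_from_edges([("A", "X", 1), ("B", "X", 2), ("C", "X", 5), ("X", "D", 3)])
        assert fn.degree_difference(net, "X") == 2
        assert fn.degree_difference(net, "A") == -1

    def test_exit_difference_equals_in_degree(self, sim60):
        net = fn.build_network(sim60.records)
        assert fn.degree_difference(net, EXIT) == net.graph.in_degree(EXIT)

    def test_absent_node_raises(self):
        net = net_from_edges([("A", "B", 1)])
        with pytest.raises(fn.NodeNotFoundError):
            fn.degree_difference(net, "Z")


class TestDegreeRoles:
    def test_constant_zero_difference_is_balanced(self):
        nets = [net_from_edges([("A", "B", 1), ("B", "A", 1)], window=f"m{i}") for i in range(3)]
        roles = {r.node: r.role for r in fn.classify_degree_roles(nets, threshold=10)}
        assert roles == {"A": ROLE_BALANCED, "B": ROLE_BALANCED}

    def test_mean_difference_beyond_threshold(self):
        senders = [f"S{i}" for i in range(15)]
        nets = [net_from_edges([(s, "HUB", 1) for s in senders], window=f"m{i}") for i in range(2)]
        roles = {r.node: r for r in fn.classify_degree_roles(nets, threshold=10)}
        assert roles["HUB"].role == ROLE_IN
        assert roles["HUB"].mean_difference == 15
        assert roles["S0"].role == ROLE_BALANCED

    def test_ae_ward_is_a_distributor_in_simulation(self, sim60):
        nets = fn.windowed_networks(sim60.records, frequency="month", site="PRUH")
        roles = {r.node: r.role for r in fn.classify_degree_roles(nets, threshold=10)}
        assert roles["AE"] == ROLE_OUT  # one entry ward feeding many wards
        assert roles[EXIT] == ROLE_IN

    def test_threshold_must_be_positive(self, sim60):
        with pytest.raises(fn.UsageError):
            fn.classify_degree_roles([fn.build_network(sim60.records)], threshold=0)


class TestWeightVariability:
    @pytest.mark.parametrize(
        "weights,expected",
        [
            ((5, 5, 5), 0.0),  # perfectly balanced
            ((1, 1, 8), 1.0),  # the extremal configuration itself
            ((2, 3, 5), 5 / 14),
            ((1, 1), 0.0),  # all-ones: maximum deviation is 0, defined as balanced
        ],
    )
    def test_reference_values(self, weights, expected):
        assert fn.weight_variability(weights) == pytest.approx(expected)

    def test_fewer_than_two_edges_undefined(self):
        with pytest.raises(fn.UndefinedScoreError):
            fn.weight_variability([7])

    def test_sub_unit_weights_rejected(self):
        with pytest.raises(fn.UndefinedScoreError):
            fn.weight_variability([0.5, 2.0])

    def test_matches_brute_force_on_exhaustive_small_vectors(self):
        for k in (2, 3):
            for w in itertools.product(range(1, 7), repeat=k):
                score = fn.weight_variability(w)
                assert score == pytest.approx(brute_force_variability(w), abs=1e-12)
                assert 0.0 <= score <= 1.0 + 1e-12

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=2, max_size=8), st.randoms())
    def test_permutation_invariance(self, weights, rnd):
        shuffled = list(weights)
        rnd.shuffle(shuffled)
        assert fn.weight_variability(shuffled) == pytest.approx(fn.weight_variability(weights))

    def test_score_is_not_scale_free(self):
        # the extremal configuration anchors weight 1, so rescaling counts
        # changes the score; this documents the intended count-based behaviour
        assert fn.weight_variability([4, 6, 10]) != pytest.approx(fn.weight_variability([2, 3, 5]))

    def test_proportion_network_scored_on_counts(self, sim60):
        count = fn.build_network(sim60.records, site="PRUH")
        prop = count.to_proportion()
        assert fn.node_variability(prop, "AE", "output") == pytest.approx(
            fn.node_variability(count, "AE", "output")
        )

    def test_simulated_scores_show_planted_skew(self, sim60):
        """High-traffic routing concentrates flow on few edges, so monthly
        variability scores should sit well above zero on average."""
        nets = [n for n in fn.windowed_networks(sim60.records, frequency="month", site="PRUH")]
        table = fn.variability_table(nets)
        assert table["score"].between(0, 1).all()
        assert table["score"].mean() > 0.5


class TestPathCentrality:
    PATHS = [
        PatientPath("p1", ("A", "B", EXIT), True, "DH"),
        PatientPath("p2", ("A", "C", EXIT), True, "DH"),
        PatientPath("p3", ("C", EXIT), True, "DH"),
    ]

    def test_fractions(self):
        assert fn.path_centrality(self.PATHS, "C") == pytest.approx(2 / 3)
        assert fn.path_centrality(self.PATHS, EXIT) == 1.0
        assert fn.path_centrality(self.PATHS, "Z") == 0.0

    def test_empty_path_set_undefined(self):
        with pytest.raises(fn.UsageError):
            fn.path_centrality([], "A")

    def test_table_covers_all_seen_wards(self):
        table = fn.path_centrality_table(self.PATHS)
        assert set(table.index) == {"A", "B", "C", EXIT}
        assert table[EXIT] == 1.0
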