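"""Random-walk edge weighting and k-shortest / near-shortest path extraction."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from p2n.core import GoAnnotation
from p2n.errors import P2NError
from p2n.netbuild import SignalingNetwork
from p2n.propagation import (
    k_shortest_paths,
    propagation_subnetwork,
    restrict_targets_by_go,
    weight_edges,
)

from conftest import make_dataset, make_net


def enumerate_paths(net, weights, source, target, k, epsilon):
    """Oracle: exhaustive simple-path enumeration, sorted by (weight, nodes),
    keeping the first k plus everything within epsilon of the optimum."""
    g = net.graph
    if source not in g or target not in g:
        return []
    all_paths = [
        (sum(weights.weights[(u, v)] for u, v in zip(p, p[1:])), tuple(p))
        for p in nx.all_simple_paths(g, source, target)
    ]
    if not all_paths:
        return []
    all_paths.sort(key=lambda wp: (wp[0], wp[1]))
    w_min = all_paths[0][0]
    return [
        wp for i, wp in enumerate(all_paths)
        if i < k or wp[0] <= w_min + epsilon + 1e-9
    ]


class TestWeighting:
    def test_forced_step_costs_zero(self):
        net = make_net([("A", "B"), ("B", "C")])
        w = weight_edges(net)
        assert w.weights[("A", "B")] == 0.0
        assert w.path_weight(("A", "B", "C")) == 0.0  # probability-1 walk

    def test_fanout_costs_log2(self):
        net = make_net([("H", f"T{i}") for i in range(8)])
        w = weight_edges(net)
        assert all(v == pytest.approx(3.0) for v in w.weights.values())

    def test_unit_scheme(self):
        net = make_net([("A", "B"), ("B", "C")])
        w = weight_edges(net, "unit")
        assert w.path_weight(("A", "B", "C")) == 2.0

    def test_unknown_scheme_rejected(self):
        with pytest.raises(P2NError):
            weight_edges(make_net([("A", "B")]), "bogus")


class TestKShortest:
    def test_unique_path_chain(self):
        net = make_net([("A", "B"), ("B", "C")])
        paths = k_shortest_paths(net, weight_edges(net), "A", "C", k=1, epsilon=0.0)
        assert [p.nodes for p in paths] == [("A", "B", "C")]

    def test_low_fanout_detour_beats_hub_shortcut(self):
        # S->H->T via a 10-out-degree hub (weight 1+log2(10)) loses to the
        # forced 3-hop detour S->a->b->T (weight 1).
        edges = [("S", "H"), ("S", "a"), ("a", "b"), ("b", "T"), ("H", "T")]
        edges += [("H", f"x{i}") for i in range(9)]
        net = make_net(edges)
        w = weight_edges(net)
        paths = k_shortest_paths(net, w, "S", "T", k=2, epsilon=0.0)
        assert paths[0].nodes == ("S", "a", "b", "T")
        assert paths[0].weight == pytest.approx(1.0)
        assert paths[1].nodes == ("S", "H", "T")
        assert paths[1].weight == pytest.approx(1.0 + math.log2(10))

    def test_unreachable_target_empty(self):
        net = make_net([("A", "B")], nodes=["C"])
        net.graph.add_edge("C", "D")
        assert k_shortest_paths(net, weight_edges(net), "A", "D", 3, 1.0) == []

    def test_near_shortest_extension_beyond_k(self):
        # three parallel 2-hop routes of equal weight: k=1 still keeps all
        edges = []
        for mid in ("M1", "M2", "M3"):
            edges += [("S", mid), (mid, "T")]
        net = make_net(edges)
        paths = k_shortest_paths(net, weight_edges(net), "S", "T", k=1, epsilon=0.0)
        assert len(paths) == 3

    def test_matches_enumeration_oracle_on_random_digraphs(self):
        rng = np.random.default_rng(99)
        for _ in range(60):
            n = int(rng.integers(4, 11))
            p = float(rng.uniform(0.2, 0.5))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)), directed=True)
            net = SignalingNetwork(nx.relabel_nodes(nx.DiGraph(g), str), "n")
            if net.graph.number_of_edges() == 0:
                continue
            w = weight_edges(net)
            nodes = sorted(net.graph.nodes)
            s, t = rng.choice(nodes, size=2, replace=False)
            k = int(rng.integers(1, 5))
            eps = float(rng.choice([0.0, 0.5, 1.0]))
            got = k_shortest_paths(net, w, str(s), str(t), k=k, epsilon=eps)
            expected = enumerate_paths(net, w, str(s), str(t), k, eps)
            assert [(p.weight, p.nodes) for p in got] == pytest.approx(expected)

    def test_unit_weighting_matches_bfs(self):
        rng = np.random.default_rng(5)
        g = nx.gnp_random_graph(12, 0.3, seed=11, directed=True)
        net = SignalingNetwork(nx.relabel_nodes(nx.DiGraph(g), str), "n")
        w = weight_edges(net, "unit")
        for s in sorted(net.graph.nodes):
            lengths = nx.single_source_shortest_path_length(net.graph, s)
            for t, hops in lengths.items():
                if t == s:
                    continue
                best = k_shortest_paths(net, w, s, t, k=1, epsilon=0.0)
                assert best[0].weight == pytest.approx(hops)

    def test_weights_nondecreasing_and_first_is_optimum(self):
        g = nx.gnp_random_graph(10, 0.4, seed=4, directed=True)
        net = SignalingNetwork(nx.relabel_nodes(nx.DiGraph(g), str), "n")
        w = weight_edges(net)
        wg = nx.DiGraph()
        for (u, v), wt in w.weights.items():
            wg.add_edge(u, v, weight=wt)
        for s in sorted(net.graph.nodes):
            dists = nx.single_source_dijkstra_path_length(wg, s)
            for t in sorted(net.graph.nodes):
                if t == s or t not in dists:
                    continue
                paths = k_shortest_paths(net, w, s, t, k=4, epsilon=0.5)
                weights = [p.weight for p in paths]
                assert weights == sorted(weights)
                assert weights[0] == pytest.approx(dists[t])


class TestPropagationSubnetwork:
    def test_shared_prefix_appears_once_with_condition_label(self):
        net = make_net([("S", "A"), ("A", "T1"), ("A", "T2")])
        w = weight_edges(net)
        ens = propagation_subnetwork(
            net, w, "S", [make_dataset("c1", ["T1", "T2"])], k=2, epsilon=0.0
        )
        assert ens.subnetwork.graph["S"]["A"]["conditions"] == {"c1"}
        assert set(ens.subnetwork.graph.nodes) == {"S", "A", "T1", "T2"}

    def test_identical_conditions_share_all_labels(self):
        net = make_net([("S", "A"), ("A", "T")])
        w = weight_edges(net)
        ens = propagation_subnetwork(
            net, w, "S",
            [make_dataset("c1", ["T"]), make_dataset("c2", ["T"])],
        )
        for _, _, d in ens.subnetwork.graph.edges(data=True):
            assert d["conditions"] == {"c1", "c2"}

    def test_condition_exclusive_edges_match_enumeration(self):
        net = make_net(
            [("S", "A"), ("A", "T1"), ("S", "B"), ("B", "T2"), ("A", "B")]
        )
        w = weight_edges(net)
        ens = propagation_subnetwork(
            net, w, "S",
            [make_dataset("c1", ["T1"]), make_dataset("c2", ["T2"])],
            k=1, epsilon=0.0,
        )
        g = ens.subnetwork.graph
        assert g["A"]["T1"]["conditions"] == {"c1"}
        assert g["B"]["T2"]["conditions"] == {"c2"}
        assert g["S"]["A"]["conditions"] == {"c1"}

    def test_no_orphan_edges_in_union(self):
        rng = np.random.default_rng(17)
        g = nx.gnp_random_graph(15, 0.25, seed=8, directed=True)
        net = SignalingNetwork(nx.relabel_nodes(nx.DiGraph(g), str), "n")
        w = weight_edges(net)
        targets = [str(i) for i in rng.choice(15, size=5, replace=False) if str(i) != "0"]
        ens = propagation_subnetwork(net, w, "0", [make_dataset("c", targets)])
        used = set()
        for tp in ens.paths["c"].values():
            for p in tp:
                used |= set(zip(p.nodes, p.nodes[1:]))
        assert set(ens.subnetwork.graph.edges) == used

    def test_unreachable_targets_recorded_not_raised(self):
        net = make_net([("S", "A"), ("X", "Y")])
        w = weight_edges(net)
        ens = propagation_subnetwork(net, w, "S", [make_dataset("c", ["Y"])])
        assert ens.unreachable["c"] == ["Y"]

    def test_direct_neighbor_shortcut_always_included(self):
        # hub S with high fanout: the 1-edge path to T is costly but kept
        edges = [("S", f"x{i}") for i in range(15)] + [("S", "T")]
        edges += [("S", "a"), ("a", "T")]
        net = make_net(edges)
        w = weight_edges(net)
        ens = propagation_subnetwork(net, w, "S", [make_dataset("c", ["T"])], k=1, epsilon=0.0)
        assert ("S", "T") in {
            p.nodes for p in ens.paths["c"]["T"]
        } or ("S", "T") in [p.nodes for p in ens.paths["c"]["T"]]
        assert any(p.nodes == ("S", "T") for p in ens.paths["c"]["T"])

    def test_absent_source_rejected(self):
        net = make_net([("A", "B")])
        with pytest.raises(P2NError):
            propagation_subnetwork(net, weight_edges(net), "Z", [])


class TestGoRestriction:
    def _go(self):
        return GoAnnotation(
            term_to_accessions={
                "GO:0007155": {"P1", "P2"},
                "GO:0008283": {"P3"},
            },
            groups={
                "adhesion-motility": {"GO:0007155", "GO:0048870"},
                "growth-death": {"GO:0008283"},
            },
        )

    def test_annotated_target_retained(self):
        ds = make_dataset("c", ["P1", "P9"])
        out = restrict_targets_by_go(ds, self._go(), "adhesion-motility")
        assert out.accessions == {"P1"}

    def test_empty_intersection_warns_but_returns(self):
        ds = make_dataset("c", ["P9"])
        out = restrict_targets_by_go(ds, self._go(), "growth-death")
        assert len(out) == 0

    def test_unknown_group_lists_options(self):
        with pytest.raises(P2NError, match="adhesion-motility"):
            restrict_targets_by_go(make_dataset("c", ["P1"]), self._go(), "nope")
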