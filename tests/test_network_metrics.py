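import networkx as nx
import numpy as np
import pytest

from mccn import (
    causal_density,
    causal_reciprocity,
    causal_score,
    graph_efficiency,
    net_causal_flow,
    node_metrics,
    powerlaw_r2,
    sigma_from_components,
    small_world_sigma,
    summarize,
    topology,
    undirected_density,
)
from mccn.errors import ValidationError
from mccn.network_metrics import annotate_nodes, reciprocated_count


def brute_force_node_indices(graph):
    """Edge-set-scan oracle for n_o, n_i, cs, ncf, per-node reciprocity."""
    edges = set(graph.edges())
    out = {}
    for v in graph.nodes():
        n_o = sum(1 for (a, _) in edges if a == v)
        n_i = sum(1 for (_, b) in edges if b == v)
        recip = sum(
            1
            for (a, b) in edges
            if (v in (a, b)) and ((b, a) in edges)
        )
        out[v] = {
            "n_o": n_o,
            "n_i": n_i,
            "cs": n_o / (n_o + n_i) if n_o + n_i else float("nan"),
            "ncf": n_o - n_i,
            "c_recip_node": recip / (n_o + n_i) if n_o + n_i else float("nan"),
        }
    return out


class TestNodeIndices:
    def test_hub_otu_degrees(self):
        # indegree 31, outdegree 16 -> cs = 16/47
        assert causal_score(16, 31) == pytest.approx(16 / 47)
        assert causal_score(16, 31) == pytest.approx(0.3404, abs=1e-4)

    def test_boundary_scores(self):
        assert causal_score(0, 5) == 0.0
        assert causal_score(7, 7) == 0.5
        assert np.isnan(causal_score(0, 0))

    def test_ncf_reduces_to_degree_difference(self):
        # ncf = (N_v - n_i) - (N_v - n_o) = n_o - n_i for any N_v
        assert net_causal_flow(13, 13) == 0
        assert net_causal_flow(21, 0) == 21

    def test_chain_and_feedback(self):
        chain = nx.DiGraph([("A", "B"), ("B", "C")])
        metrics = node_metrics(chain)
        assert list(metrics["ncf"]) == [1, 0, -1]
        assert causal_reciprocity(chain) == 0.0

        pair = nx.DiGraph([("A", "B"), ("B", "A")])
        assert causal_reciprocity(pair) == 1.0
        assert list(node_metrics(pair)["ncf"]) == [0, 0]
        assert list(node_metrics(pair)["c_recip_node"]) == [1.0, 1.0]

    def test_matches_brute_force_on_random_digraphs(self):
        for s in range(100):
            g = nx.gnp_random_graph(
                int(np.random.default_rng(s).integers(5, 41)),
                0.15,
                seed=s,
                directed=True,
            )
            oracle = brute_force_node_indices(g)
            metrics = node_metrics(g)
            for v in g.nodes():
                row = metrics.loc[v]
                assert row["outdegree"] == oracle[v]["n_o"]
                assert row["indegree"] == oracle[v]["n_i"]
                assert row["ncf"] == oracle[v]["ncf"]
                if oracle[v]["n_o"] + oracle[v]["n_i"]:
                    assert row["cs"] == oracle[v]["cs"]
                    assert row["c_recip_node"] == oracle[v]["c_recip_node"]

    def test_mean_ncf_is_zero_on_any_digraph(self):
        for s in range(20):
            g = nx.gnp_random_graph(25, 0.2, seed=1000 + s, directed=True)
            assert node_metrics(g)["ncf"].mean() == 0

    def test_annotate_nodes_round_trip(self):
        g = nx.DiGraph([("A", "B"), ("B", "A"), ("A", "C")])
        annotate_nodes(g)
        assert g.nodes["A"]["ncf"] == 1
        assert g.nodes["C"]["cs"] == 0.0


class TestNetworkIndices:
    def test_reference_causal_densities(self):
        assert round(causal_density(1856, 98), 3) == 0.098
        assert round(causal_density(730, 81), 3) == 0.056
        assert round(causal_density(441, 73), 3) == 0.042
        assert causal_density(0, 10) == 0.0

    def test_reference_graph_efficiencies(self):
        # discriminates the N(N-1) denominator from C(N,2)
        assert round(graph_efficiency(1856, 98), 3) == 0.815
        assert round(graph_efficiency(730, 81), 3) == 0.900
        assert round(graph_efficiency(441, 73), 3) == 0.930

    def test_reference_undirected_density_and_neighbors(self):
        assert round(undirected_density(3856, 98), 3) == 0.811
        assert round(undirected_density(2644, 97), 3) == 0.568
        assert round(2 * 3856 / 98, 3) == 78.694

    def test_reciprocity_matches_edge_scan(self):
        for s in range(100):
            g = nx.gnp_random_graph(30, 0.1, seed=2000 + s, directed=True)
            if g.number_of_edges() == 0:
                continue
            edges = set(g.edges())
            oracle = sum(1 for (a, b) in edges if (b, a) in edges)
            assert reciprocated_count(g) == oracle
            assert causal_reciprocity(g) == oracle / len(edges)

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            causal_density(5, 1)
        with pytest.raises(ValidationError):
            graph_efficiency(5, 1)


class TestTopology:
    def test_triangle(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "a")])
        t = topology(g)
        assert t["avg_clustering"] == pytest.approx(1.0)
        assert t["avg_shortest_path"] == pytest.approx(1.0)
        assert t["diameter"] == 1

    def test_star(self):
        g = nx.star_graph(3)
        t = topology(g)
        assert t["avg_clustering"] == 0.0
        assert t["diameter"] == 2

    def test_directed_reachable_pairs_only(self):
        g = nx.DiGraph([("a", "b"), ("b", "c")])
        t = topology(g)
        # reachable ordered pairs: a->b (1), a->c (2), b->c (1)
        assert t["avg_shortest_path"] == pytest.approx(4 / 3)
        assert t["diameter"] == 2
        assert t["radius"] == 1


class TestPowerLaw:
    def test_exact_power_law_is_r2_one(self):
        degrees = []
        for d in (1, 2, 4, 8):  # 64 * d**-2 is an exact integer count
            degrees.extend([d] * (64 // d**2))
        assert powerlaw_r2(degrees) == pytest.approx(1.0, abs=1e-9)

    def test_uniform_frequencies_fit_poorly(self):
        degrees = [d for d in range(1, 11) for _ in range(5)]
        assert powerlaw_r2(degrees) < 0.5

    def test_single_degree_value_is_missing(self):
        assert powerlaw_r2([3, 3, 3, 3]) is None


class TestSmallWorld:
    def test_sigma_identity_on_reference_components(self):
        assert round(sigma_from_components(0.449, 2.149, 0.196, 1.823), 3) == 1.943
        assert round(sigma_from_components(0.373, 2.647, 0.119, 2.210), 3) == 2.617

    def test_randomization_preserves_all_degrees(self):
        from mccn.network_metrics import _randomize

        g = nx.gnp_random_graph(20, 0.2, seed=3, directed=True)
        for rep in range(5):
            h = _randomize(g, rep, swaps_per_edge=10)
            assert dict(h.in_degree()) == dict(g.in_degree())
            assert dict(h.out_degree()) == dict(g.out_degree())

    def test_random_graph_has_sigma_near_one(self):
        g = nx.gnp_random_graph(30, 0.15, seed=5, directed=True)
        result = small_world_sigma(g, n_random=20, seed=7)
        assert result.sigma == pytest.approx(1.0, abs=0.2)

    def test_too_small_graph_rejected(self):
        with pytest.raises(ValidationError):
            small_world_sigma(nx.DiGraph([("a", "b")]))


class TestSummarize:
    def test_directed_summary_fields(self):
        g = nx.gnp_random_graph(15, 0.3, seed=9, directed=True)
        s = summarize(g)
        assert s["cd"] == causal_density(g.number_of_edges(), 15)
        assert s["ge"] == graph_efficiency(g.number_of_edges(), 15)
        assert 0 <= s["avg_cs"] <= 1
        assert "density" not in s

    def test_undirected_summary_fields(self):
        g = nx.gnp_random_graph(15, 0.3, seed=9)
        s = summarize(g)
        assert s["density"] == undirected_density(g.number_of_edges(), 15)
        assert "cd" not in s
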