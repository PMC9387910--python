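"""Causal network indices and topology diagnostics.

Per node (degrees from the directed graph; N_v = distinct neighbors):

    cs      = n_o / (n_o + n_i)        causal score, 1 = pure influencer
    ncf     = n_o − n_i                net causal flow (equivalently
                                       (N_v − n_i) − (N_v − n_o))
    c_recip = reciprocated incident links / (n_o + n_i)

Per network (n directed links over N connected nodes):

    cd      = n / (2 N (N − 1))        causal density
    ge      = 1 − (n − (N − 1)) / (N (N − 1))   graph efficiency
    c_recip = n_recip / n              fraction of links whose reverse exists

The graph-efficiency denominator is N(N−1): that is the only reading that
reproduces the reference values this index was defined with, and it equals
the number of ordered node pairs a directed spanning structure competes
against.

Topology follows the conventions of desktop network tools: clustering is the
Watts–Strogatz local coefficient on the undirected projection (degree < 2
contributes 0); shortest paths, diameter and radius are directed, averaged /
extremized over reachable ordered pairs only.  Small-world sigma compares
the graph with degree-preserving randomizations (directed edge swaps):
sigma = (C / C_rand) / (L / L_rand), > 1 suggesting small-world structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- node level

def causal_score(n_o: int, n_i: int) -> float:
    """cs = n_o / (n_o + n_i); NaN for an isolated node."""
    total = n_o + n_i
    if total == 0:
        return float("nan")
    return n_o / total


def net_causal_flow(n_o: int, n_i: int) -> int:
    """ncf = n_o − n_i (net outdegree minus net indegree collapses to this)."""
    return n_o - n_i


_NODE_COLUMNS = (
    "otu_id", "outdegree", "indegree", "n_neighbors", "cs", "ncf",
    "c_recip_node",
)


def node_metrics(graph: nx.DiGraph) -> pd.DataFrame:
    """Per-node indices: degrees, distinct neighbors, cs, ncf, c_recip."""
    if graph.number_of_nodes() == 0:
        return pd.DataFrame(columns=_NODE_COLUMNS).set_index("otu_id")
    und = graph.to_undirected(as_view=False)
    rows = []
    for node in sorted(graph.nodes()):
        n_o = graph.out_degree(node)
        n_i = graph.in_degree(node)
        recip = sum(
            1 for nbr in graph.successors(node) if graph.has_edge(nbr, node)
        ) + sum(
            1 for nbr in graph.predecessors(node) if graph.has_edge(node, nbr)
        )
        total = n_o + n_i
        rows.append(
            {
                "otu_id": node,
                "outdegree": n_o,
                "indegree": n_i,
                "n_neighbors": und.degree(node),
                "cs": causal_score(n_o, n_i),
                "ncf": net_causal_flow(n_o, n_i),
                "c_recip_node": recip / total if total else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("otu_id")


def annotate_nodes(graph: nx.DiGraph) -> nx.DiGraph:
    """Store the per-node indices as node attributes (for GraphML export)."""
    metrics = node_metrics(graph)
    for node, row in metrics.iterrows():
        graph.nodes[node].update(
            outdegree=int(row["outdegree"]),
            indegree=int(row["indegree"]),
            n_neighbors=int(row["n_neighbors"]),
            cs=float(row["cs"]),
            ncf=int(row["ncf"]),
            c_recip_node=float(row["c_recip_node"]),
        )
    return graph


# ------------------------------------------------------------- network level

def causal_density(n: int, N: int) -> float:
    """cd = n / (2 N (N − 1))."""
    if N < 2:
        raise ValidationError(f"causal density needs N >= 2, got {N}")
    return n / (2 * N * (N - 1))


def graph_efficiency(n: int, N: int) -> float:
    """ge = 1 − (n − (N − 1)) / (N (N − 1))."""
    if N < 2:
        raise ValidationError(f"graph efficiency needs N >= 2, got {N}")
    return 1.0 - (n - (N - 1)) / (N * (N - 1))


def undirected_density(n: int, N: int) -> float:
    """Undirected network density n / C(N, 2)."""
    if N < 2:
        raise ValidationError(f"density needs N >= 2, got {N}")
    return n / (N * (N - 1) / 2)


def reciprocated_count(graph: nx.DiGraph) -> int:
    """Number of directed links whose reverse link also exists."""
    return sum(1 for u, v in graph.edges() if graph.has_edge(v, u))


def causal_reciprocity(graph: nx.DiGraph) -> float:
    """c_recip = n_recip / n; NaN on an empty graph."""
    n = graph.number_of_edges()
    if n == 0:
        return float("nan")
    return reciprocated_count(graph) / n


def topology(graph: nx.DiGraph | nx.Graph) -> dict:
    """Clustering, path lengths, eccentricity summaries, neighbor counts."""
    if graph.number_of_nodes() == 0:
        raise ValidationError("topology of an empty graph is undefined")
    und = nx.Graph(graph.to_undirected()) if graph.is_directed() else graph
    avg_clustering = nx.average_clustering(und)
    lengths = dict(nx.all_pairs_shortest_path_length(graph))
    path_sum = 0
    path_count = 0
    eccentricities = []
    for src, dists in lengths.items():
        reach = [d for tgt, d in dists.items() if tgt != src]
        if reach:
            path_sum += sum(reach)
            path_count += len(reach)
            eccentricities.append(max(reach))
    return {
        "avg_clustering": avg_clustering,
        "avg_shortest_path": path_sum / path_count if path_count else float("nan"),
        "diameter": max(eccentricities) if eccentricities else 0,
        "radius": min(eccentricities) if eccentricities else 0,
        "avg_neighbors": (
            2 * und.number_of_edges() / und.number_of_nodes()
        ),
    }


def powerlaw_r2(degree_sequence) -> float | None:
    """R^2 of OLS on (log degree, log frequency); None below 3 usable bins.

    Zero-frequency and zero-degree bins are excluded (log undefined).  A low
    R^2 indicates the degree distribution is not scale-free.
    """
    degrees = np.asarray(list(degree_sequence), dtype=int)
    degrees = degrees[degrees > 0]
    if degrees.size == 0:
        return None
    values, counts = np.unique(degrees, return_counts=True)
    if values.size < 3:
        return None
    if np.ptp(counts) == 0:
        return 0.0  # perfectly flat frequencies: no power-law signal at all
    fit = stats.linregress(np.log(values), np.log(counts))
    return float(fit.rvalue**2)


# ----------------------------------------------------------- small-world sigma

def sigma_from_components(
    c: float, l: float, c_rand: float, l_rand: float
) -> float:
    """sigma = (C / C_rand) / (L / L_rand)."""
    return (c / c_rand) / (l / l_rand)


@dataclass
class SmallWorldResult:
    sigma: float
    clustering: float
    avg_shortest_path: float
    clustering_rand: float
    avg_shortest_path_rand: float
    clustering_rand_sd: float
    avg_shortest_path_rand_sd: float
    n_random: int


def _randomize(graph: nx.DiGraph | nx.Graph, rng_seed: int, swaps_per_edge: int):
    """Degree-preserving randomization via edge swaps (in/out preserved)."""
    h = graph.copy()
    m = h.number_of_edges()
    nswap = swaps_per_edge * m
    try:
        if h.is_directed():
            nx.directed_edge_swap(
                h, nswap=nswap, max_tries=100 * nswap, seed=rng_seed
            )
        else:
            nx.double_edge_swap(
                h, nswap=nswap, max_tries=100 * nswap, seed=rng_seed
            )
    except nx.NetworkXAlgorithmError:
        # ran out of admissible swaps; the partial mixing is still a valid
        # degree-preserving randomization
        log.warning("edge-swap budget exhausted before %d swaps", nswap)
    return h


def small_world_sigma(
    graph: nx.DiGraph | nx.Graph,
    n_random: int = 100,
    seed: int | None = None,
    swaps_per_edge: int = 10,
) -> SmallWorldResult:
    """Small-world sigma against an ensemble of degree-preserving rewirings."""
    if graph.number_of_nodes() < 10:
        raise ValidationError(
            f"small-world sigma needs >= 10 nodes, got {graph.number_of_nodes()}"
        )
    min_edges = 3 if graph.is_directed() else 2
    if graph.number_of_edges() < min_edges:
        raise ValidationError(
            "graph too sparse to rewire; reduce the swap count or skip sigma"
        )
    topo = topology(graph)
    rng = np.random.default_rng(seed)
    cs, ls = [], []
    for _ in range(n_random):
        h = _randomize(graph, int(rng.integers(2**31 - 1)), swaps_per_edge)
        t = topology(h)
        cs.append(t["avg_clustering"])
        ls.append(t["avg_shortest_path"])
    c_rand = float(np.mean(cs))
    l_rand = float(np.mean(ls))
    return SmallWorldResult(
        sigma=sigma_from_components(
            topo["avg_clustering"], topo["avg_shortest_path"], c_rand, l_rand
        ),
        clustering=topo["avg_clustering"],
        avg_shortest_path=topo["avg_shortest_path"],
        clustering_rand=c_rand,
        avg_shortest_path_rand=l_rand,
        clustering_rand_sd=float(np.std(cs, ddof=1)) if n_random > 1 else 0.0,
        avg_shortest_path_rand_sd=(
            float(np.std(ls, ddof=1)) if n_random > 1 else 0.0
        ),
        n_random=n_random,
    )


# ------------------------------------------------------------------ summaries

def summarize(
    graph: nx.DiGraph | nx.Graph,
    n_random: int = 0,
    seed: int | None = None,
) -> dict:
    """Network-level metric table for one graph (directed or undirected).

    ``n_random > 0`` adds the small-world sigma (stochastic, seeded); the
    directed causal indices are reported only for directed graphs, the plain
    density only for undirected ones.
    """
    n_nodes = graph.number_of_nodes()
    n_links = graph.number_of_edges()
    out: dict = {"network_size": n_nodes, "links": n_links}
    if n_nodes == 0:
        return out
    out.update(topology(graph))
    if graph.is_directed():
        out["cd"] = causal_density(n_links, n_nodes) if n_nodes >= 2 else float("nan")
        out["ge"] = graph_efficiency(n_links, n_nodes) if n_nodes >= 2 else float("nan")
        out["c_recip"] = causal_reciprocity(graph)
        nm = node_metrics(graph)
        out["avg_cs"] = float(nm["cs"].mean())
        out["powerlaw_r2_in"] = powerlaw_r2(d for _, d in graph.in_degree())
        out["powerlaw_r2_out"] = powerlaw_r2(d for _, d in graph.out_degree())
    else:
        out["density"] = (
            undirected_density(n_links, n_nodes) if n_nodes >= 2 else float("nan")
        )
        out["powerlaw_r2"] = powerlaw_r2(d for _, d in graph.degree())
    if n_random > 0 and n_nodes >= 10:
        sw = small_world_sigma(graph, n_random=n_random, seed=seed)
        out.update(
            sigma=sw.sigma,
            clustering_rand=sw.clustering_rand,
            avg_shortest_path_rand=sw.avg_shortest_path_rand,
            clustering_rand_sd=sw.clustering_rand_sd,
            avg_shortest_path_rand_sd=sw.avg_shortest_path_rand_sd,
        )
    return out
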