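"""Assemble causal, correlation and fused (MCCN) networks.

The causal network (MGCN / BoMGCN, depending on the threshold) is a directed
graph with an edge j → i per accepted Granger link; a pair significant in
both directions is marked bidirectional (feedback).  The correlation network
(MCN / BoMCN) is undirected with signed Spearman rho weights.  The MCCN keeps
a causal edge only when its unordered pair also carries a significant
correlation, attaches the rho sign/weight, and classifies each linked pair
into an ecological interaction type:

    bidirectional + positive rho  → mutualism_synergism
    unidirectional + positive rho → commensalism
    unidirectional + negative rho → amensalism
    bidirectional + negative rho  → competition
    no causal link                → neutralism

Predation/parasitism would show as a negative bidirectional link between a
consumer and its prey, but 16S data carries no protozoa or phages, so that
label is deliberately never emitted; rho exactly zero alongside a causal
edge is logged as ``unresolved``.  Network "size" counts connected nodes
only: isolated nodes are dropped when edges are filtered away.
"""

from __future__ import annotations

import itertools
import logging

import networkx as nx
import numpy as np
import pandas as pd

from .causality import CausalityMatrix
from .correlation import CorrelationMatrix
from .errors import ValidationError
from .multiple_testing import ThresholdResult

log = logging.getLogger(__name__)

INTERACTION_LABELS = (
    "mutualism_synergism",
    "commensalism",
    "amensalism",
    "competition",
    "neutralism",
    "unresolved",
)

UNIDIRECTIONAL = "unidirectional"
BIDIRECTIONAL = "bidirectional"


def classify_interaction(
    pair_directionality: str | None, rho_sign: int | float | None
) -> str:
    """Map (directionality, correlation sign) to an interaction label.

    ``pair_directionality`` is ``"unidirectional"``, ``"bidirectional"`` or
    ``None`` (no causal link in either direction); ``rho_sign`` is the sign
    of the significant Spearman rho (+1, −1, 0) or ``None`` when the pair has
    no significant correlation.  Pure function, total over its domain.
    """
    if pair_directionality is None:
        return "neutralism"
    if pair_directionality not in (UNIDIRECTIONAL, BIDIRECTIONAL):
        raise ValidationError(
            f"unknown directionality {pair_directionality!r}"
        )
    if rho_sign is None:
        # causal link without correlation support: no interaction evidence
        return "neutralism"
    sign = np.sign(rho_sign)
    if sign == 0:
        log.warning("causal pair with rho exactly 0: unresolved")
        return "unresolved"
    if pair_directionality == BIDIRECTIONAL:
        return "mutualism_synergism" if sign > 0 else "competition"
    return "commensalism" if sign > 0 else "amensalism"


def _mark_directionality(graph: nx.DiGraph) -> None:
    for u, v in graph.edges():
        graph.edges[u, v]["directionality"] = (
            BIDIRECTIONAL if graph.has_edge(v, u) else UNIDIRECTIONAL
        )


def _attach_taxonomy(graph, taxonomy) -> None:
    if taxonomy:
        for node in graph.nodes():
            if node in taxonomy:
                graph.nodes[node]["taxonomy"] = taxonomy[node]


def build_causal_network(
    cmatrix: CausalityMatrix,
    threshold: ThresholdResult,
    taxonomy: dict[str, str] | None = None,
) -> nx.DiGraph:
    """Directed graph of accepted Granger links; isolated nodes dropped."""
    graph = nx.DiGraph(
        provenance=f"causal:{threshold.method}", alpha=threshold.alpha
    )
    if threshold.alpha_star is not None:
        graph.graph["alpha_star"] = threshold.alpha_star
    for (src, tgt) in sorted(threshold.accepted_links):
        j = cmatrix.otu_ids.index(src)
        i = cmatrix.otu_ids.index(tgt)
        graph.add_edge(
            src, tgt,
            granger_p=float(cmatrix.p[j, i]),
            lag=int(cmatrix.lag[j, i]),
        )
    _mark_directionality(graph)
    _attach_taxonomy(graph, taxonomy)
    log.info(
        "causal network (%s): %d nodes, %d links",
        threshold.method, graph.number_of_nodes(), graph.number_of_edges(),
    )
    return graph


def build_correlation_network(
    rmatrix: CorrelationMatrix,
    threshold: ThresholdResult,
    taxonomy: dict[str, str] | None = None,
) -> nx.Graph:
    """Undirected graph of accepted correlations with signed rho weights."""
    graph = nx.Graph(
        provenance=f"correlation:{threshold.method}", alpha=threshold.alpha
    )
    if threshold.alpha_star is not None:
        graph.graph["alpha_star"] = threshold.alpha_star
    pairs = rmatrix.pair_map()
    for pair in sorted(threshold.accepted_links):
        rho, p = pairs[tuple(pair)]
        graph.add_edge(
            *pair, spearman_rho=rho, spearman_p=p, sign=int(np.sign(rho))
        )
    _attach_taxonomy(graph, taxonomy)
    log.info(
        "correlation network (%s): %d nodes, %d links",
        threshold.method, graph.number_of_nodes(), graph.number_of_edges(),
    )
    return graph


def fuse_mccn(g_causal: nx.DiGraph, g_corr: nx.Graph) -> nx.DiGraph:
    """Keep causal edges whose pair also has a significant correlation.

    Fusion only removes: the MCCN edge set is a subset of the causal edge
    set.  Each surviving edge gains the pair's rho (sign and weight) and an
    interaction label; nodes left isolated are dropped.
    """
    fused = nx.DiGraph(
        provenance=(
            f"mccn({g_causal.graph.get('provenance')} + "
            f"{g_corr.graph.get('provenance')})"
        )
    )
    for u, v, attrs in g_causal.edges(data=True):
        if not g_corr.has_edge(u, v):
            continue
        corr = g_corr.edges[u, v]
        fused.add_edge(
            u, v, **attrs,
            spearman_rho=corr["spearman_rho"],
            spearman_p=corr["spearman_p"],
        )
    _mark_directionality(fused)
    for u, v, attrs in fused.edges(data=True):
        attrs["interaction_label"] = classify_interaction(
            attrs["directionality"], attrs["spearman_rho"]
        )
    for node, tax in g_causal.nodes(data="taxonomy"):
        if tax is not None and fused.has_node(node):
            fused.nodes[node]["taxonomy"] = tax
    log.info(
        "MCCN: %d nodes, %d links",
        fused.number_of_nodes(), fused.number_of_edges(),
    )
    return fused


def interaction_table(graph: nx.DiGraph) -> pd.DataFrame:
    """One row per linked unordered pair of the MCCN with its label."""
    rows = []
    seen: set[frozenset] = set()
    for u, v, attrs in graph.edges(data=True):
        key = frozenset((u, v))
        if key in seen:
            continue
        seen.add(key)
        rows.append(
            {
                "source": u,
                "target": v,
                "directionality": attrs.get("directionality"),
                "spearman_rho": attrs.get("spearman_rho"),
                "interaction_label": attrs.get("interaction_label"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "source", "target", "directionality", "spearman_rho",
            "interaction_label",
        ],
    )


def neutral_pairs(otu_ids: list[str], g_causal: nx.DiGraph) -> pd.DataFrame:
    """Pairs with no causal link in either direction (neutralism).

    Neutral pairs have no edge to carry a label, so they are reported as a
    separate pair-level table rather than as graph edges.
    """
    rows = []
    for a, b in itertools.combinations(sorted(otu_ids), 2):
        if not g_causal.has_edge(a, b) and not g_causal.has_edge(b, a):
            rows.append(
                {"otu_a": a, "otu_b": b, "interaction_label": "neutralism"}
            )
    return pd.DataFrame(rows, columns=["otu_a", "otu_b", "interaction_label"])


def interaction_counts(graph: nx.DiGraph) -> dict[str, int]:
    """Label → number of linked pairs carrying it."""
    table = interaction_table(graph)
    counts = dict.fromkeys(INTERACTION_LABELS, 0)
    for label in table["interaction_label"]:
        counts[label] += 1
    return counts
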