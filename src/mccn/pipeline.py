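"""End-to-end driver: filter → stationarity → Granger → correlation →
thresholds → networks → interaction labels → metrics.

Every stage is a pure function of (input table, configuration, seed); the
run manifest records every parameter and per-stage count so a rerun with an
identical manifest reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field

import networkx as nx
import numpy as np

from . import __version__
from .causality import all_pairs_causality
from .correlation import spearman_all_pairs
from .io_formats import AbundanceTable
from .multiple_testing import threshold_links
from .network_build import (
    build_causal_network,
    build_correlation_network,
    fuse_mccn,
    interaction_counts,
    interaction_table,
    neutral_pairs,
)
from .network_metrics import annotate_nodes, node_metrics, summarize
from .preprocessing import filter_otus, make_stationary, to_relative_abundance

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable parameters of a run, with the method's defaults."""

    prevalence_min: float = 0.80
    rel_abund_min: float = 1e-4
    alpha_stationary: float = 0.05
    max_rounds: int = 2
    max_lag: int = 5
    criterion: str = "aic"
    alpha: float = 0.05
    fdr_crit: float = 0.05
    causal_threshold: str = "bonferroni"   # threshold behind the MCCN fusion
    corr_threshold: str = "bonferroni"
    use_differenced_corr: bool = False
    skip_filter: bool = False
    n_random: int = 100
    seed: int = 42

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            setattr(cfg, key, type(getattr(cfg, key))(value))
        return cfg


@dataclass
class PipelineResult:
    """All artifacts of one run plus the manifest."""

    relative_table: AbundanceTable
    stationary: object
    causality: object
    correlation: object
    thresholds: dict
    networks: dict            # mgcn / bomgcn / mcn / bomcn / mccn
    interactions: object      # pair-level DataFrame with labels
    neutral: object           # neutral-pair DataFrame
    node_metrics: object
    network_metrics: dict
    manifest: dict = field(default_factory=dict)


def _table_hash(table: AbundanceTable) -> str:
    h = hashlib.sha256()
    h.update(",".join(table.otu_ids).encode())
    h.update(",".join(table.time_labels).encode())
    h.update(np.ascontiguousarray(table.matrix).tobytes())
    return h.hexdigest()[:16]


def run_all(table: AbundanceTable, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full network-inference pipeline on one abundance table."""
    cfg = config or PipelineConfig()
    t0 = time.perf_counter()
    manifest: dict = {
        "tool_version": __version__,
        "input_hash": _table_hash(table),
        "parameters": asdict(cfg),
        "counts": {},
    }
    counts = manifest["counts"]
    counts["input_otus"] = table.n_otus
    counts["time_points"] = table.n_timepoints

    rel_full = to_relative_abundance(table)
    if cfg.skip_filter:
        retained = table.otu_ids
    else:
        retained = filter_otus(
            table, cfg.prevalence_min, cfg.rel_abund_min
        ).otu_ids
    rel = rel_full.subset(retained)
    counts["otus_after_filter"] = len(retained)

    sset = make_stationary(
        rel, alpha=cfg.alpha_stationary, max_rounds=cfg.max_rounds
    )
    counts["otus_stationary"] = sset.n_otus
    counts["otus_differenced"] = sum(
        1 for d in sset.diff_order.values() if d > 0
    )
    counts["otus_nonstationary"] = len(sset.nonstationary_ids)

    cmat = all_pairs_causality(
        sset, max_lag=cfg.max_lag, criterion=cfg.criterion
    )
    counts["pairs_skipped"] = len(cmat.skipped_pairs)

    corr_input = sset if cfg.use_differenced_corr else rel.subset(sset.otu_ids)
    rmat = spearman_all_pairs(corr_input, use_differenced=cfg.use_differenced_corr)

    k = sset.n_otus
    p_causal = cmat.p_map()
    p_corr = {pair: p for pair, (_, p) in rmat.pair_map().items()}
    thresholds = {
        "causal_raw": threshold_links(p_causal, "raw", alpha=cfg.alpha),
        "causal_bonferroni": threshold_links(
            p_causal, "bonferroni", alpha=cfg.alpha, n_otus=k
        ),
        "causal_fdr": threshold_links(
            p_causal, "fdr", alpha=cfg.alpha, fdr_crit=cfg.fdr_crit
        ),
        "corr_raw": threshold_links(p_corr, "raw", alpha=cfg.alpha),
        "corr_bonferroni": threshold_links(
            p_corr, "bonferroni", alpha=cfg.alpha, n_otus=k
        ),
    }

    taxonomy = table.taxonomy
    networks = {
        "mgcn": build_causal_network(cmat, thresholds["causal_raw"], taxonomy),
        "bomgcn": build_causal_network(
            cmat, thresholds["causal_bonferroni"], taxonomy
        ),
        "mcn": build_correlation_network(rmat, thresholds["corr_raw"], taxonomy),
        "bomcn": build_correlation_network(
            rmat, thresholds["corr_bonferroni"], taxonomy
        ),
    }
    causal_for_mccn = {
        "raw": networks["mgcn"],
        "bonferroni": networks["bomgcn"],
        "fdr": build_causal_network(cmat, thresholds["causal_fdr"], taxonomy),
    }[cfg.causal_threshold]
    corr_for_mccn = {
        "raw": networks["mcn"],
        "bonferroni": networks["bomcn"],
    }[cfg.corr_threshold]
    mccn = fuse_mccn(causal_for_mccn, corr_for_mccn)
    annotate_nodes(mccn)
    networks["mccn"] = mccn

    for name, g in networks.items():
        counts[f"{name}_nodes"] = g.number_of_nodes()
        counts[f"{name}_links"] = g.number_of_edges()

    interactions = interaction_table(mccn)
    neutral = neutral_pairs(sset.otu_ids, causal_for_mccn)
    counts["interaction_counts"] = interaction_counts(mccn)
    counts["neutral_pairs"] = len(neutral)

    metrics = {}
    for name, g in networks.items():
        if g.number_of_edges() == 0:
            metrics[name] = {"network_size": 0, "links": 0}
            continue
        metrics[name] = summarize(
            g,
            n_random=cfg.n_random if name in ("mgcn", "bomgcn", "mccn") else 0,
            seed=cfg.seed,
        )
    nmetrics = node_metrics(mccn) if mccn.number_of_nodes() else None

    manifest["wall_time_s"] = round(time.perf_counter() - t0, 3)
    manifest["output_hash"] = hashlib.sha256(
        json.dumps(
            {
                name: sorted(map(list, g.edges()))
                for name, g in networks.items()
            },
            sort_keys=True,
        ).encode()
    ).hexdigest()[:16]
    return PipelineResult(
        relative_table=rel,
        stationary=sset,
        causality=cmat,
        correlation=rmat,
        thresholds=thresholds,
        networks=networks,
        interactions=interactions,
        neutral=neutral,
        node_metrics=nmetrics,
        network_metrics=metrics,
        manifest=manifest,
    )
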