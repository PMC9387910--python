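"""OTU-table and network I/O.

The on-disk contracts are deliberately plain text:

* OTU table — TSV or CSV; first column = OTU identifier, remaining numeric
  columns = ordered time points, optional trailing ``taxonomy`` column with a
  rank-delimited lineage string (kept opaque apart from splitting on ``;``).
* Edge list — one row per directed edge with the Granger p-value, selected
  lag, Spearman rho/p, the pair-level directionality and the interaction
  label; directly importable into Cytoscape.
* GraphML — same graph with node attributes, via :mod:`networkx`.

Floats are serialized with the shortest decimal representation that restores
the exact binary value (never fewer than the digits needed, at least 12
significant digits whenever they matter), so a write/read round-trip is
lossless.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, ValidationError

log = logging.getLogger(__name__)


EDGE_COLUMNS = (
    "source",
    "target",
    "granger_p",
    "lag",
    "spearman_rho",
    "spearman_p",
    "directionality",
    "interaction_label",
)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and math.isnan(value):
        return ""
    if isinstance(value, (float, np.floating)):
        return repr(float(value))  # shortest exact decimal round-trip
    return str(value)


@dataclass
class AbundanceTable:
    """An OTU-by-time abundance matrix.

    Rows are OTUs, columns are strictly time-ordered samples.  Values may be
    raw counts or relative abundances; they must be finite and non-negative,
    and missing cells are an error (never imputed).
    """

    otu_ids: list[str]
    time_labels: list[str]
    matrix: np.ndarray
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        k, t = self.matrix.shape if self.matrix.ndim == 2 else (0, 0)
        if self.matrix.ndim != 2:
            raise ValidationError("abundance matrix must be 2-dimensional")
        if len(self.otu_ids) != k:
            raise ValidationError(
                f"{len(self.otu_ids)} OTU ids for {k} matrix rows"
            )
        if len(self.time_labels) != t:
            raise ValidationError(
                f"{len(self.time_labels)} time labels for {t} matrix columns"
            )
        if t < 3:
            raise ValidationError(f"need at least 3 time points, got {t}")
        if len(set(self.otu_ids)) != k:
            seen: set[str] = set()
            dup = next(o for o in self.otu_ids if o in seen or seen.add(o))
            raise ValidationError(f"duplicate OTU id {dup!r}")
        if not np.all(np.isfinite(self.matrix)):
            i, j = np.argwhere(~np.isfinite(self.matrix))[0]
            raise ValidationError(
                f"non-finite value for OTU {self.otu_ids[i]!r} "
                f"at time {self.time_labels[j]!r}"
            )
        if np.any(self.matrix < 0):
            i, j = np.argwhere(self.matrix < 0)[0]
            raise ValidationError(
                f"negative abundance for OTU {self.otu_ids[i]!r} "
                f"at time {self.time_labels[j]!r}"
            )

    @property
    def n_otus(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[1]

    def series(self, otu_id: str) -> np.ndarray:
        return self.matrix[self.otu_ids.index(otu_id)]

    def subset(self, keep: Iterable[str]) -> "AbundanceTable":
        keep = list(keep)
        idx = [self.otu_ids.index(o) for o in keep]
        tax = (
            {o: self.taxonomy[o] for o in keep if o in self.taxonomy}
            if self.taxonomy
            else None
        )
        return AbundanceTable(keep, list(self.time_labels), self.matrix[idx], tax)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=self.otu_ids, columns=self.time_labels
        )


@dataclass
class EdgeRecord:
    """One directed edge as written to / read from an edge list."""

    source: str
    target: str
    granger_p: float | None = None
    lag: int | None = None
    spearman_rho: float | None = None
    spearman_p: float | None = None
    directionality: str | None = None
    interaction_label: str | None = None


def _sniff_sep(path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if "\t" in head else ","


def read_otu_table(path, orientation_hint: str = "otus_as_rows") -> AbundanceTable:
    """Read a TSV/CSV OTU table.

    ``orientation_hint`` is ``"otus_as_rows"`` (default) or
    ``"otus_as_columns"`` for transposed files; auto-detection is deliberately
    not attempted.
    """
    if orientation_hint not in ("otus_as_rows", "otus_as_columns"):
        raise ValidationError(f"unknown orientation_hint {orientation_hint!r}")
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if orientation_hint == "otus_as_columns":
        df = df.T
    taxonomy = None
    if df.columns.size and str(df.columns[-1]).lower() == "taxonomy":
        taxonomy = df.iloc[:, -1].to_dict()
        df = df.iloc[:, :-1]
    otu_ids = [str(o) for o in df.index]
    if len(set(otu_ids)) != len(otu_ids):
        seen: set[str] = set()
        dup = next(o for o in otu_ids if o in seen or seen.add(o))
        raise ParseError(f"duplicate OTU id {dup!r} in {path}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df.iloc[:, j]):
            try:
                values[i, j] = float(raw)
            except (TypeError, ValueError):
                raise ParseError(
                    f"non-numeric cell {raw!r} at OTU {otu_ids[i]!r}, "
                    f"column {col!r} in {path}"
                ) from None
    table = AbundanceTable(
        otu_ids, [str(c) for c in df.columns], values, taxonomy
    )
    log.info(
        "read %d OTUs x %d time points from %s", table.n_otus,
        table.n_timepoints, path,
    )
    return table


def write_otu_table(table: AbundanceTable, path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        header = ["#OTU_ID", *table.time_labels]
        if table.taxonomy:
            header.append("taxonomy")
        fh.write(sep.join(header) + "\n")
        for i, otu in enumerate(table.otu_ids):
            row = [otu, *(_fmt(v) for v in table.matrix[i])]
            if table.taxonomy:
                row.append(table.taxonomy.get(otu, ""))
            fh.write(sep.join(row) + "\n")


def split_lineage(taxonomy: str) -> list[str]:
    """Split a rank-delimited lineage string on ';' for display."""
    return [part.strip() for part in taxonomy.split(";") if part.strip()]


def write_edge_list(graph: nx.DiGraph | nx.Graph, path, sep: str = "\t") -> None:
    """Write one row per directed edge (Cytoscape-importable TSV)."""
    with open(path, "w") as fh:
        fh.write(sep.join(EDGE_COLUMNS) + "\n")
        for u, v, attrs in sorted(graph.edges(data=True)):
            row = [str(u), str(v)] + [
                _fmt(attrs.get(col)) for col in EDGE_COLUMNS[2:]
            ]
            fh.write(sep.join(row) + "\n")
    log.info("wrote %d edges to %s", graph.number_of_edges(), path)


def read_edge_list(path, sep: str = "\t") -> nx.DiGraph:
    """Read an edge list written by :func:`write_edge_list`."""
    graph = nx.DiGraph()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
        if header[:2] != ["source", "target"]:
            raise ParseError(f"{path} is not an edge list (header {header!r})")
        for line in fh:
            fields = line.rstrip("\n").split(sep)
            rec = dict(zip(header, fields))
            attrs: dict = {}
            for key in ("granger_p", "spearman_rho", "spearman_p"):
                if rec.get(key):
                    attrs[key] = float(rec[key])
            if rec.get("lag"):
                attrs["lag"] = int(rec["lag"])
            for key in ("directionality", "interaction_label"):
                if rec.get(key):
                    attrs[key] = rec[key]
            graph.add_edge(rec["source"], rec["target"], **attrs)
    return graph


def write_graphml(graph: nx.DiGraph | nx.Graph, path) -> None:
    """Write GraphML, dropping ``None``/NaN attributes GraphML cannot carry."""
    clean = graph.__class__()
    clean.graph.update(
        {k: v for k, v in graph.graph.items() if isinstance(v, (str, int, float))}
    )
    for node, attrs in graph.nodes(data=True):
        clean.add_node(
            node, **{k: v for k, v in attrs.items() if _keepable(v)}
        )
    for u, v, attrs in graph.edges(data=True):
        clean.add_edge(
            u, v, **{k: w for k, w in attrs.items() if _keepable(w)}
        )
    nx.write_graphml(clean, path)


def _keepable(value) -> bool:
    if value is None:
        return False
    if isinstance(value, float) and math.isnan(value):
        return False
    return isinstance(value, (str, int, float, np.integer, np.floating, bool))


def load_config(path) -> dict:
    """Load a flat YAML (or key: value) config file into a dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ParseError(f"config {path} must be a flat mapping")
    return cfg
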