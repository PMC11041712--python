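"""Consensus miRNA-target selection and interaction-graph degree statistics.

A gene qualifies as a consensus target when it is predicted by at least two
of three algorithms (TaPmiR counting only when its binding probability is
strictly above 0.95, TargetScan, miRDB) or carries experimental validation
evidence.  The selected targets form the node set of a simple undirected
protein-protein interaction graph for which descriptive degree statistics
are reported (node/edge counts, average degree 2E/N over all nodes
including isolated ones, maximum degree, top-degree nodes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "ALGORITHMS",
    "TAPMIR_PROBABILITY_THRESHOLD",
    "TargetPredictionRecord",
    "consensus_targets",
    "degree_stats",
    "read_edge_list",
    "read_prediction_csv",
    "build_graph",
]

ALGORITHMS = frozenset({"TaPmiR", "TargetScan", "miRDB"})

#: TaPmiR predictions count toward the consensus only above this probability.
TAPMIR_PROBABILITY_THRESHOLD = 0.95


class NetworkInputError(ValueError):
    pass


@dataclass(frozen=True)
class TargetPredictionRecord:
    """Per-gene prediction/validation evidence across the three algorithms."""

    gene_symbol: str
    predicted_by: frozenset[str] = field(default_factory=frozenset)
    tapmir_probability: float | None = None
    validated: bool = False

    def __post_init__(self) -> None:
        preds = frozenset(self.predicted_by)
        unknown = preds - ALGORITHMS
        if unknown:
            raise NetworkInputError(
                f"{self.gene_symbol}: unknown algorithm(s) {sorted(unknown)}"
            )
        object.__setattr__(self, "predicted_by", preds)
        if self.tapmir_probability is not None and not (
            0.0 <= self.tapmir_probability <= 1.0
        ):
            raise NetworkInputError(
                f"{self.gene_symbol}: probability outside [0, 1]"
            )

    def qualifying_algorithms(
        self, tapmir_threshold: float = TAPMIR_PROBABILITY_THRESHOLD
    ) -> frozenset[str]:
        quals = set(self.predicted_by - {"TaPmiR"})
        if "TaPmiR" in self.predicted_by:
            if self.tapmir_probability is not None and self.tapmir_probability > tapmir_threshold:
                quals.add("TaPmiR")
        return frozenset(quals)


def consensus_targets(
    records: Sequence[TargetPredictionRecord],
    min_algorithms: int = 2,
    tapmir_threshold: float = TAPMIR_PROBABILITY_THRESHOLD,
) -> set[str]:
    """Genes predicted by >= ``min_algorithms`` qualifying algorithms or validated."""
    out = set()
    for rec in records:
        if rec.validated or len(rec.qualifying_algorithms(tapmir_threshold)) >= min_algorithms:
            out.add(rec.gene_symbol)
    return out


def build_graph(
    edges: Iterable[tuple[str, str]],
    nodes: Iterable[str] | None = None,
) -> nx.Graph:
    """Simple undirected graph; self-loops rejected, duplicates collapsed."""
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for u, v in edges:
        if u == v:
            warnings.warn(f"self-loop {u!r} ignored", stacklevel=2)
            continue
        g.add_edge(u, v)
    return g


def degree_stats(graph: nx.Graph, n_top: int = 3) -> dict:
    """Descriptive degree statistics of an interaction graph.

    Average degree is 2E/N over every node, counting isolated targets.
    ``top_nodes`` lists the ``n_top`` highest-degree nodes (ties broken by
    name) as (node, degree) pairs.
    """
    if graph.number_of_nodes() == 0:
        raise NetworkInputError("empty graph")
    if any(u == v for u, v in graph.edges()):
        raise NetworkInputError("graph contains self-loops")
    n_nodes = graph.number_of_nodes()
    n_edges = graph.number_of_edges()
    degrees = dict(graph.degree())
    ranked = sorted(degrees.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return {
        "n_nodes": n_nodes,
        "n_edges": n_edges,
        "avg_degree": 2.0 * n_edges / n_nodes,
        "max_degree": max(degrees.values()),
        "top_nodes": ranked[:n_top],
    }


def read_edge_list(path, nodes: Iterable[str] | None = None) -> nx.Graph:
    """Read a two-column whitespace/TSV edge list into a deduplicated graph.

    ``nodes`` optionally adds isolated nodes so that degree statistics cover
    the full target set.
    """
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise NetworkInputError(f"{path}:{lineno}: expected two columns")
            edges.append((parts[0], parts[1]))
    return build_graph(edges, nodes=nodes)


def read_prediction_csv(path) -> list[TargetPredictionRecord]:
    """Read a gene x algorithm indicator table.

    Columns: ``gene_symbol``, one 0/1 column per algorithm (``TaPmiR``,
    ``TargetScan``, ``miRDB``), optional ``tapmir_probability`` and
    ``validated``.
    """
    df = pd.read_csv(path)
    if "gene_symbol" not in df.columns:
        raise NetworkInputError("prediction CSV missing gene_symbol column")
    algo_cols = [c for c in df.columns if c in ALGORITHMS]
    if not algo_cols:
        raise NetworkInputError("prediction CSV has no algorithm columns")
    if df["gene_symbol"].duplicated().any():
        raise NetworkInputError("duplicate gene symbols in prediction table")
    out = []
    for row in df.itertuples(index=False):
        preds = frozenset(c for c in algo_cols if bool(getattr(row, c)))
        prob = getattr(row, "tapmir_probability", None)
        prob = None if prob is None or pd.isna(prob) else float(prob)
        out.append(
            TargetPredictionRecord(
                gene_symbol=str(row.gene_symbol),
                predicted_by=preds,
                tapmir_probability=prob,
                validated=bool(getattr(row, "validated", False)),
            )
        )
    return out
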