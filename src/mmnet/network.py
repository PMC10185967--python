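"""Stratified multimorbidity networks: support-weighted edges, node strength.

Nodes are the 15 diseases; the undirected edge weight between two diseases
is the pair's support (co-occurrence proportion, 0–1 scale), and a node's
*strength* is the sum of its supports over all 14 partners. Strength is
always computed over the full pair set, so it is invariant to the display
edge threshold, which only filters the exported edge list.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import Cohort
from .panel import DISEASES, StratumSpec
from .rules import PairCounts, pair_counts

GRAPH_FORMATS = ("edge-list", "graphml")


@dataclass(frozen=True)
class NetworkSummary:
    """Per-disease prevalence and strength plus support-weighted edges."""

    stratum: str
    nodes: pd.DataFrame          # index disease; columns prevalence, strength
    edges: pd.DataFrame          # columns u, v, support (all pairs, untresholded)
    edge_threshold: float = 0.0

    def display_edges(self) -> pd.DataFrame:
        """Edges at or above the display threshold (and strictly positive)."""
        e = self.edges
        keep = (e["support"] >= self.edge_threshold) & (e["support"] > 0)
        return e[keep].reset_index(drop=True)

    def to_networkx(self, thresholded: bool = True) -> nx.Graph:
        g = nx.Graph(stratum=self.stratum, edge_threshold=float(self.edge_threshold))
        for disease, row in self.nodes.iterrows():
            g.add_node(disease, prevalence=float(row["prevalence"]),
                       strength=float(row["strength"]))
        edges = self.display_edges() if thresholded else self.edges
        for r in edges.itertuples(index=False):
            g.add_edge(r.u, r.v, support=float(r.support))
        return g


def network_from_counts(counts: PairCounts, edge_threshold: float = 0.0) -> NetworkSummary:
    """Build the network summary from the integer count layer."""
    names = list(counts.marginals.index)
    n = counts.n
    support = counts.joint.to_numpy(dtype=float) / n
    np.fill_diagonal(support, 0.0)
    strength = support.sum(axis=1)
    prevalence = counts.marginals.to_numpy(dtype=float) / n
    nodes = pd.DataFrame(
        {"prevalence": prevalence, "strength": strength},
        index=pd.Index(names, name="disease"),
    )
    rows = [
        {"u": names[i], "v": names[j], "support": support[i, j]}
        for i in range(len(names))
        for j in range(i + 1, len(names))
    ]
    return NetworkSummary(
        stratum=counts.stratum,
        nodes=nodes,
        edges=pd.DataFrame(rows, columns=["u", "v", "support"]),
        edge_threshold=edge_threshold,
    )


def build_network(
    cohort: Cohort,
    stratum: StratumSpec = StratumSpec(),
    edge_threshold: float = 0.0,
) -> NetworkSummary:
    """Network of one stratum: prevalences, supports, full-sum node strengths."""
    return network_from_counts(pair_counts(cohort, stratum), edge_threshold)


def strength_ranking(network: NetworkSummary) -> list[str]:
    """Diseases by descending node strength, ties broken alphabetically."""
    nodes = network.nodes.reset_index()
    nodes = nodes.sort_values(by=["strength", "disease"], ascending=[False, True],
                              kind="mergesort")
    return list(nodes["disease"])


# ---------------------------------------------------------------------------
# serialization

def export_graph(network: NetworkSummary, path: str | Path, format: str = "graphml") -> None:
    """Write the thresholded display graph (plus node attributes) to disk.

    ``graphml`` keeps everything in one schema-valid file; ``edge-list``
    writes ``<path>`` as a u,v,support CSV and ``<path>.nodes.csv`` with the
    per-disease attribute table. Node strengths are stored from the full
    (untresholded) support sums.
    """
    fmt = format.lower()
    if fmt not in GRAPH_FORMATS:
        raise ValueError(f"unknown graph format {format!r}; choose from {GRAPH_FORMATS}")
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(network.to_networkx(thresholded=True), path)
    else:
        network.display_edges().to_csv(path, index=False)
        network.nodes.to_csv(path.with_suffix(path.suffix + ".nodes.csv"))


def import_graphml(path: str | Path) -> NetworkSummary:
    """Round-trip companion of :func:`export_graph` for GraphML output.

    Edges below the stored display threshold are absent from the file by
    design; node prevalences and strengths are recovered exactly.
    """
    g = nx.read_graphml(path)
    nodes = pd.DataFrame(
        {
            "prevalence": {d: g.nodes[d]["prevalence"] for d in g.nodes},
            "strength": {d: g.nodes[d]["strength"] for d in g.nodes},
        }
    ).reindex(list(DISEASES))
    nodes.index.name = "disease"
    rows = [
        {"u": min(u, v), "v": max(u, v), "support": d["support"]}
        for u, v, d in g.edges(data=True)
    ]
    edges = pd.DataFrame(rows, columns=["u", "v", "support"])
    edges = edges.sort_values(["u", "v"]).reset_index(drop=True)
    return NetworkSummary(
        stratum=g.graph.get("stratum", "all_all"),
        nodes=nodes,
        edges=edges,
        edge_threshold=float(g.graph.get("edge_threshold", 0.0)),
    )
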