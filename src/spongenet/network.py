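"""Assembly and interrogation of the miRNA-mediated interaction (MMI) network.

Nodes are mRNAs and lncRNAs with highly correlated expression; each edge is
labelled by the miRNA mediating the interaction, so a pair connected
through several miRNAs carries parallel edges and node degree counts
parallel edges separately (a hub's edge count exceeds its neighbour
count).  The graph is undirected: competition for a shared miRNA is
symmetric.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .stats import SpongeTriplet

logger = logging.getLogger(__name__)


@dataclass
class MMINetwork:
    """A multigraph of mRNA/lncRNA nodes with miRNA-labelled edges."""

    graph: nx.MultiGraph = field(default_factory=nx.MultiGraph)
    provenance: dict = field(default_factory=dict)

    # -- construction -------------------------------------------------
    def add_edge(self, a: str, role_a: str, b: str, role_b: str, mirna_id: str) -> None:
        if a == b:
            raise ValueError(f"self-interaction rejected for node {a!r}")
        self.graph.add_node(a, role=role_a)
        self.graph.add_node(b, role=role_b)
        # at most one edge per (pair, miRNA)
        self.graph.add_edge(a, b, key=mirna_id, mirna=mirna_id)

    # -- queries ------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    def edges(self) -> list[tuple[str, str, str]]:
        """Edges as (node_a, node_b, mirna_id) with endpoints sorted."""
        return [
            (*sorted((a, b)), k) for a, b, k in self.graph.edges(keys=True)
        ]

    def nodes_with_role(self, role: str) -> list[str]:
        return [n for n, r in self.graph.nodes(data="role") if r == role]

    def neighbors(self, node: str) -> list[str]:
        return list(self.graph.neighbors(node))


def build_network(
    triplets: Sequence[SpongeTriplet],
    enrichment_alpha: float = 0.01,
    provenance: dict | None = None,
) -> MMINetwork:
    """Build the MMI network from enrichment-annotated sponge triplets.

    One edge per triplet with enrichment p strictly below ``alpha`` and at
    least one match site in both the mRNA's 3'UTR and the lncRNA
    transcript.  Triplets with identical endpoints are rejected with a
    warning.  The result is independent of triplet order.
    """
    net = MMINetwork(provenance=dict(provenance or {}, enrichment_alpha=enrichment_alpha))
    kept = 0
    for t in triplets:
        if t.x_id == t.y_id:
            logger.warning("triplet with identical endpoints dropped: %s", t.x_id)
            continue
        if t.enrichment_p is None or t.shared_site_counts is None:
            raise ValueError("triplets must carry enrichment results")
        if t.enrichment_p < enrichment_alpha and min(t.shared_site_counts) >= 1:
            net.add_edge(t.x_id, "mRNA", t.y_id, "lncRNA", t.z_id)
            kept += 1
    logger.info(
        "network build: %d/%d triplets kept -> %d nodes, %d edges",
        kept, len(triplets), net.n_nodes, net.n_edges,
    )
    return net


def top_hubs(net: MMINetwork, k: int) -> list[tuple[str, int]]:
    """The k highest-degree nodes; ties broken lexicographically by id."""
    if k <= 0:
        raise ValueError("k must be positive")
    if net.n_nodes == 0:
        raise ValueError("network is empty")
    ranked = sorted(net.graph.degree, key=lambda nd: (-nd[1], nd[0]))
    return ranked[:k]


def mirna_edge_fraction(net: MMINetwork, node: str, mirna_set: Iterable[str]) -> float:
    """Fraction of a node's edges mediated by any miRNA in the given set."""
    if node not in net.graph:
        raise KeyError(f"node {node!r} not in network")
    deg = net.degree(node)
    if deg == 0:
        return float("nan")
    mirnas = set(mirna_set)
    hits = sum(
        1 for _, _, m in net.graph.edges(node, keys=True) if m in mirnas
    )
    return hits / deg


def neighborhood(net: MMINetwork, node: str) -> MMINetwork:
    """The star sub-network of a node: itself, its edges and its neighbours."""
    if node not in net.graph:
        raise KeyError(f"node {node!r} not in network")
    sub = MMINetwork(provenance=dict(net.provenance, center=node))
    role = net.graph.nodes[node].get("role", "")
    for _, nb, m in net.graph.edges(node, keys=True):
        sub.add_edge(node, role, nb, net.graph.nodes[nb].get("role", ""), m)
    if sub.n_nodes == 0:
        sub.graph.add_node(node, role=role)
    return sub


def compare_networks(net_a: MMINetwork, net_b: MMINetwork) -> dict:
    """Rewiring summary between two networks (e.g. normal vs cancer).

    Reports shared/unique node and (pair, miRNA) edge counts, Jaccard
    indices for both, and per-node degree deltas (b minus a).
    """
    nodes_a = set(net_a.graph.nodes)
    nodes_b = set(net_b.graph.nodes)
    edges_a = set(net_a.edges())
    edges_b = set(net_b.edges())

    def jaccard(s, t):
        return len(s & t) / len(s | t) if (s | t) else 1.0

    deltas = {
        n: net_b.degree(n) if n in nodes_b else 0
        for n in nodes_a | nodes_b
    }
    for n in deltas:
        deltas[n] -= net_a.degree(n) if n in nodes_a else 0
    return {
        "nodes_shared": len(nodes_a & nodes_b),
        "nodes_only_a": len(nodes_a - nodes_b),
        "nodes_only_b": len(nodes_b - nodes_a),
        "edges_shared": len(edges_a & edges_b),
        "edges_only_a": len(edges_a - edges_b),
        "edges_only_b": len(edges_b - edges_a),
        "node_jaccard": jaccard(nodes_a, nodes_b),
        "edge_jaccard": jaccard(edges_a, edges_b),
        "degree_delta": deltas,
    }


def export_network(net: MMINetwork, path: str | Path, fmt: str = "edgelist") -> None:
    """Write the network as an edge-list TSV or as GraphML."""
    path = Path(path)
    if fmt == "edgelist":
        rows = [
            {
                "node_a": a,
                "node_b": b,
                "mirna_id": m,
                "role_a": net.graph.nodes[a].get("role", ""),
                "role_b": net.graph.nodes[b].get("role", ""),
            }
            for a, b, m in sorted(net.edges())
        ]
        pd.DataFrame(
            rows, columns=["node_a", "node_b", "mirna_id", "role_a", "role_b"]
        ).to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        nx.write_graphml(net.graph, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def read_network(path: str | Path, fmt: str = "edgelist") -> MMINetwork:
    """Read a network written by :func:`export_network`."""
    path = Path(path)
    if fmt == "edgelist":
        net = MMINetwork()
        table = pd.read_csv(path, sep="\t", dtype=str)
        for row in table.itertuples():
            net.add_edge(row.node_a, row.role_a, row.node_b, row.role_b, row.mirna_id)
        return net
    if fmt == "graphml":
        g = nx.read_graphml(path, force_multigraph=True)
        net = MMINetwork()
        for a, b, data in g.edges(data=True):
            net.add_edge(
                a, g.nodes[a].get("role", ""), b, g.nodes[b].get("role", ""),
                data["mirna"],
            )
        return net
    raise ValueError(f"unknown format {fmt!r}")


def summary(net: MMINetwork, k: int = 10) -> dict:
    """Machine-readable network summary (counts, hubs, per-miRNA tallies)."""
    per_mirna: dict[str, int] = {}
    for _, _, m in net.edges():
        per_mirna[m] = per_mirna.get(m, 0) + 1
    return {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "n_mrna": len(net.nodes_with_role("mRNA")),
        "n_lncrna": len(net.nodes_with_role("lncRNA")),
        "top_hubs": top_hubs(net, min(k, net.n_nodes)) if net.n_nodes else [],
        "edges_per_mirna": dict(sorted(per_mirna.items(), key=lambda kv: -kv[1])),
        "provenance": net.provenance,
    }


def write_summary(net: MMINetwork, path: str | Path, k: int = 10) -> None:
    with open(path, "w") as fh:
        json.dump(summary(net, k), fh, indent=2, default=str)
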