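"""Merged regulatory networks, subnetworks and degree topology.

Merging the FFLs of one category yields that category's subnetwork
(miRNA-SNW, TF-SNW, composite-SNW); merging all three yields the full
regulatory network.  Only FFL-participating nodes and edges enter a
network — predicted edges that join no FFL are excluded by construction.
Degree is undirected total degree (incident edge count); a reciprocal
TF↔miRNA pair is two distinct edges and contributes 2 to each endpoint.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ffl import FFL, FFLCategory
from .io import EdgeType, NodeClass, RegulatoryEdge

logger = logging.getLogger(__name__)

__all__ = ["RegulatoryNetwork", "merge_ffls", "degree_table", "network_summary"]


@dataclass
class RegulatoryNetwork:
    """Union of nodes and edges over a set of FFLs."""

    nodes: dict[str, NodeClass]
    edges: set[RegulatoryEdge]
    provenance: frozenset[FFLCategory] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.edges)


def merge_ffls(
    ffls: Sequence[FFL],
    categories: Iterable[FFLCategory] | None = None,
) -> RegulatoryNetwork:
    """Union the nodes and edges of all FFLs in the selected categories.

    With all categories (the default) this is the full network; with a
    single category it is the corresponding subnetwork.
    """
    cats = frozenset(categories) if categories is not None else frozenset(FFLCategory)
    nodes: dict[str, NodeClass] = {}
    edges: set[RegulatoryEdge] = set()
    contributed: set[FFLCategory] = set()
    for f in ffls:
        if f.category not in cats:
            continue
        contributed.add(f.category)
        nodes[f.mirna] = NodeClass.MIRNA
        nodes[f.tf] = NodeClass.TF
        nodes[f.gene] = NodeClass.GENE
        edges.update(f.edges)
    if not edges:
        logger.warning("merge_ffls produced an empty network")
    return RegulatoryNetwork(nodes=nodes, edges=edges, provenance=frozenset(contributed))


def degree_table(network: RegulatoryNetwork) -> pd.DataFrame:
    """Undirected incident-edge count per node: columns node, node_class, degree."""
    deg: Counter[str] = Counter()
    for e in network.edges:
        deg[e.source] += 1
        deg[e.target] += 1
    rows = [
        {"node": n, "node_class": cls.value, "degree": deg.get(n, 0)}
        for n, cls in sorted(network.nodes.items())
    ]
    return pd.DataFrame(rows, columns=["node", "node_class", "degree"])


def network_summary(
    network: RegulatoryNetwork,
    rosters: Mapping[NodeClass, int] | None = None,
) -> dict:
    """Node counts by class and edge counts by type, with optional
    fraction-of-roster percentages when roster sizes are supplied."""
    nodes_by_class = Counter(cls.value for cls in network.nodes.values())
    edges_by_type = Counter(e.edge_type.value for e in network.edges)
    out: dict = {
        "n_nodes": len(network.nodes),
        "n_edges": len(network.edges),
        "nodes_by_class": {c.value: nodes_by_class.get(c.value, 0) for c in NodeClass},
        "edges_by_type": {t.value: edges_by_type.get(t.value, 0) for t in EdgeType},
    }
    if rosters:
        out["roster_percent"] = {
            cls.value: round(100.0 * nodes_by_class.get(cls.value, 0) / size, 2)
            for cls, size in rosters.items()
            if size
        }
    return out
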