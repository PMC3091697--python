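"""Direct-interaction-network assembly over regulated genes plus seed nodes.

Given a curated edge table (source, target, interaction type, directed
flag) and a member list — the regulated genes plus declared seed nodes
such as the zinc ion itself and Mtf1 — the network is the induced
subgraph: an edge survives iff both endpoints are members.  Hubs are
ranked by degree counted as unique neighbours regardless of edge type or
direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .preprocess import ConfigurationError

log = logging.getLogger(__name__)

EDGE_TYPES = ("binding", "expression", "regulation", "metabolism", "promoter binding")


@dataclass
class InteractionNetwork:
    """Typed interaction graph with explicit isolated-member bookkeeping."""

    graph: nx.Graph  # nodes carry 'seed' flag; edges carry 'type', 'directed'
    isolated: set = field(default_factory=set)
    n_duplicates: int = 0
    n_skipped: int = 0

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list:
        return [
            (u, v, d["type"], d["directed"]) for u, v, d in self.graph.edges(data=True)
        ]

    def connected_components(self) -> list:
        return sorted(
            (sorted(c) for c in nx.connected_components(self.graph)),
            key=len,
            reverse=True,
        )


def build_direct_interaction_network(
    members, seed_nodes, edge_table: pd.DataFrame
) -> InteractionNetwork:
    """Induce the curated-interaction subgraph on members plus seed nodes.

    ``edge_table`` needs columns source, target, type, directed (bool-ish).
    Malformed rows are skipped with a warning count; duplicate
    (source, target, type) triples collapse to a single edge.  Members
    touching no surviving edge are kept as isolated, flagged nodes.
    """
    keep = set(members) | set(seed_nodes)
    if not keep:
        raise ConfigurationError("member and seed sets are both empty")
    g = nx.Graph()
    for node in keep:
        g.add_node(node, seed=node in set(seed_nodes))
    n_dup = n_skip = 0
    seen: set = set()
    for row in edge_table.itertuples(index=False):
        try:
            u, v, etype = row.source, row.target, row.type
            if not all(isinstance(x, str) and x for x in (u, v, etype)):
                raise ValueError("empty or non-string field")
            directed = bool(row.directed)
        except (AttributeError, ValueError):
            n_skip += 1
            continue
        if u not in keep or v not in keep:
            continue
        key = (u, v, etype) if directed else (min(u, v), max(u, v), etype)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        # undirected container: a second type between the same pair keeps
        # the first edge's attributes; degree ranking only needs adjacency
        if not g.has_edge(u, v):
            g.add_edge(u, v, type=etype, directed=directed)
    if n_skip:
        log.warning("skipped %d malformed edge rows", n_skip)
    isolated = {n for n in keep if g.degree(n) == 0}
    return InteractionNetwork(graph=g, isolated=isolated, n_duplicates=n_dup, n_skipped=n_skip)


def rank_hubs(network: InteractionNetwork) -> pd.DataFrame:
    """Degree table (unique neighbours), descending, ties broken by node id."""
    rows = [(n, network.graph.degree(n)) for n in network.graph.nodes]
    out = pd.DataFrame(rows, columns=["node", "degree"])
    return out.sort_values(["degree", "node"], ascending=[False, True], ignore_index=True)


def export_graphml(network: InteractionNetwork, path) -> None:
    nx.write_graphml(network.graph, path)
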