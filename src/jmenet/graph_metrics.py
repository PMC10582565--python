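"""Whole-brain signed network construction, centralities, communities, layout.

The network is an undirected graph over the controlled region vocabulary.
Nodes are brain regions; an edge is present when at least one retained
study reports a connectivity change for the pair.  Edges carry a sign
(+1 increased / -1 decreased in patients, where studies are unanimous) and
a multiplicity (number of supporting records).

Degree centrality CD(i) counts a node's distinct neighbours.  Betweenness
centrality CB(i) measures the share of shortest paths between other node
pairs that run through i; the default is the fractional (Brandes) form
normalised by (g-1)(g-2)/2 so values lie in [0, 1], with a literal
raw-path-count mode available for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .literature_model import (
    CONNECTIVITY_INDICATORS,
    ConnectivityChangeRecord,
    RecordSet,
    qualitative_direction,
)

logger = logging.getLogger(__name__)


class GraphMetricsError(ValueError):
    pass


class BrainNetwork:
    """Undirected region graph with optional per-edge sign and multiplicity.

    Thin wrapper over :class:`networkx.Graph`; edge attributes are ``sign``
    (+1/-1, absent when studies disagree or signs are unknown) and
    ``multiplicity`` (supporting record count, default 1).
    """

    def __init__(self, graph: nx.Graph | None = None) -> None:
        g = graph if graph is not None else nx.Graph()
        if any(u == v for u, v in g.edges):
            raise GraphMetricsError("self-loops are not allowed")
        self.graph = g

    # -- construction -------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        signs: Mapping[tuple[str, str], int] | None = None,
        nodes: Iterable[str] | None = None,
    ) -> "BrainNetwork":
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        for u, v in edges:
            g.add_edge(u, v, multiplicity=1)
        if signs:
            for (u, v), s in signs.items():
                if not g.has_edge(u, v):
                    raise GraphMetricsError(f"sign given for non-edge ({u}, {v})")
                g.edges[u, v]["sign"] = int(s)
        return cls(g)

    # -- views ---------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted((u, v))) for u, v in self.graph.edges}

    @property
    def edge_sign(self) -> dict[tuple[str, str], int]:
        return {
            tuple(sorted((u, v))): d["sign"]
            for u, v, d in self.graph.edges(data=True)
            if "sign" in d
        }

    @property
    def edge_multiplicity(self) -> dict[tuple[str, str], int]:
        return {
            tuple(sorted((u, v))): d.get("multiplicity", 1)
            for u, v, d in self.graph.edges(data=True)
        }

    def induced(self, nodes: Iterable[str]) -> "BrainNetwork":
        return BrainNetwork(self.graph.subgraph(nodes).copy())

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __repr__(self) -> str:
        return (
            f"BrainNetwork(n_nodes={self.graph.number_of_nodes()}, "
            f"n_edges={self.graph.number_of_edges()})"
        )

    # -- I/O -------------------------------------------------------------
    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))

    @classmethod
    def from_graphml(cls, path: str | Path) -> "BrainNetwork":
        return cls(nx.read_graphml(str(path)))

    def to_edgelist_csv(self, path: str | Path) -> None:
        rows = [
            {
                "region_a": min(u, v),
                "region_b": max(u, v),
                "sign": d.get("sign", ""),
                "multiplicity": d.get("multiplicity", 1),
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        rows.sort(key=lambda r: (r["region_a"], r["region_b"]))
        pd.DataFrame(
            rows, columns=["region_a", "region_b", "sign", "multiplicity"]
        ).to_csv(path, index=False)

    @classmethod
    def from_edgelist_csv(cls, path: str | Path) -> "BrainNetwork":
        df = pd.read_csv(path)
        g = nx.Graph()
        for row in df.to_dict(orient="records"):
            attrs: dict = {"multiplicity": int(row.get("multiplicity", 1) or 1)}
            sign = row.get("sign")
            if sign not in (None, "") and not pd.isna(sign):
                attrs["sign"] = int(sign)
            g.add_edge(str(row["region_a"]), str(row["region_b"]), **attrs)
        return cls(g)


@dataclass(frozen=True)
class CentralityProfile:
    """Per-node degree and betweenness values for one network."""

    degree: dict[str, int]
    betweenness: dict[str, float]       # normalised to [0, 1]
    raw_betweenness: dict[str, float]


@dataclass(frozen=True)
class CommunityAssignment:
    """Label-propagation community labels, contiguous ids from 0."""

    labels: dict[str, int]
    n_communities: int
    seed: int


def build_network(
    records: RecordSet,
    include_indicators: frozenset[str] | set[str] = CONNECTIVITY_INDICATORS,
    sign_threshold: float = 0.0,
) -> BrainNetwork:
    """Build the whole-brain network from merged, conflict-resolved records.

    One edge per region pair with at least one retained record; the edge
    sign is set where all supporting records agree; multiplicity counts
    supporting records.  Only nodes appearing in some record are included.
    """
    kept = [r for r in records if r.indicator in include_indicators]
    if not kept:
        raise GraphMetricsError(
            "cannot build a network from an empty record set "
            "(after indicator filtering)"
        )
    g = nx.Graph()
    by_pair: dict[tuple[str, str], list[ConnectivityChangeRecord]] = {}
    for rec in kept:
        by_pair.setdefault(rec.pair, []).append(rec)
    for (a, b), recs in sorted(by_pair.items()):
        signs = {qualitative_direction(r, threshold=sign_threshold) for r in recs}
        attrs: dict = {"multiplicity": len(recs)}
        if len(signs) == 1:
            attrs["sign"] = signs.pop()
        g.add_edge(a, b, **attrs)
    return BrainNetwork(g)


def degree_centrality(
    net: BrainNetwork, mode: str = "simple"
) -> dict[str, int]:
    """CD per node: distinct neighbours (``simple``) or record-weighted
    (``multiplicity``, summing supporting records over incident edges)."""
    if mode == "simple":
        return {n: d for n, d in net.graph.degree()}
    if mode == "multiplicity":
        return {
            n: sum(d.get("multiplicity", 1) for _, _, d in net.graph.edges(n, data=True))
            for n in net.graph.nodes
        }
    raise ValueError(f"unknown degree mode {mode!r}")


def betweenness_centrality(
    net: BrainNetwork, normalized: bool = True, mode: str = "fractional"
) -> dict[str, float]:
    """CB per node.

    ``fractional`` (default): Brandes betweenness, each {j, k} pair
    contributing the fraction of its shortest paths through i; normalised
    form divides by (g-1)(g-2)/2.  ``raw-count``: the literal count of
    shortest paths through i, summed over unordered pairs (provided for
    comparison; not normalisable to [0, 1]).
    Disconnected pairs contribute 0.
    """
    if mode == "fractional":
        return dict(nx.betweenness_centrality(net.graph, normalized=normalized))
    if mode == "raw-count":
        counts = {n: 0.0 for n in net.graph.nodes}
        nodes = sorted(net.graph.nodes)
        for idx, j in enumerate(nodes):
            for k in nodes[idx + 1 :]:
                try:
                    paths = list(nx.all_shortest_paths(net.graph, j, k))
                except nx.NetworkXNoPath:
                    continue
                for p in paths:
                    for mid in p[1:-1]:
                        counts[mid] += 1.0
        return counts
    raise ValueError(f"unknown betweenness mode {mode!r}")


def centrality_profile(
    net: BrainNetwork, degree_mode: str = "simple"
) -> CentralityProfile:
    """Degree plus fractional betweenness (raw and normalised) for a network."""
    return CentralityProfile(
        degree=degree_centrality(net, mode=degree_mode),
        betweenness=betweenness_centrality(net, normalized=True),
        raw_betweenness=betweenness_centrality(net, normalized=False),
    )


def label_propagation(net: BrainNetwork, seed: int) -> CommunityAssignment:
    """Asynchronous label propagation with seeded node order and tie-breaking.

    Each node starts with a unique label and repeatedly adopts a (randomly
    tie-broken) majority label of its neighbours, in seeded random order,
    until every node's label is maximal among its neighbours.  Deterministic
    given the seed; disconnected components can never share a label.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        return CommunityAssignment(labels={}, n_communities=0, seed=seed)
    # rebuild with canonical node/edge insertion order: the asynchronous
    # sweep depends on iteration order, and the contract is determinism
    # from (graph content, seed) alone
    canon = nx.Graph()
    canon.add_nodes_from(sorted(g.nodes, key=str))
    canon.add_edges_from(
        sorted((min(u, v, key=str), max(u, v, key=str)) for u, v in g.edges)
    )
    communities = list(nx.community.asyn_lpa_communities(canon, seed=seed))
    # contiguous ids, deterministic order by smallest member
    communities.sort(key=lambda c: min(c))
    labels = {n: i for i, comm in enumerate(communities) for n in comm}
    return CommunityAssignment(
        labels=labels, n_communities=len(communities), seed=seed
    )


def spring_layout(net: BrainNetwork, seed: int) -> dict[str, np.ndarray]:
    """Force-directed 2-D layout, deterministic given seed; finite coordinates."""
    if len(net) == 1:
        (node,) = net.graph.nodes
        return {node: np.zeros(2)}
    pos = nx.spring_layout(net.graph, seed=seed)
    for node, xy in pos.items():
        if not np.all(np.isfinite(xy)):
            raise GraphMetricsError(f"non-finite layout coordinate for {node}")
    return pos


def centrality_table(net: BrainNetwork, degree_mode: str = "simple") -> pd.DataFrame:
    """Tidy per-node centrality table (``node,degree,cb_raw,cb_norm``)."""
    prof = centrality_profile(net, degree_mode=degree_mode)
    rows = [
        {
            "node": n,
            "degree": prof.degree[n],
            "cb_raw": prof.raw_betweenness[n],
            "cb_norm": prof.betweenness[n],
        }
        for n in sorted(net.graph.nodes)
    ]
    return pd.DataFrame(rows, columns=["node", "degree", "cb_raw", "cb_norm"])
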