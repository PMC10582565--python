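"""White-matter-tract-constrained sign-consistency analysis of the core network.

Anatomy constrains which functional edges are admissible: a tract map
declares which core region pairs have a direct fiber connection.  Observed
connectivity changes are signed (+1 increased, -1 decreased); along a chain
of fiber-connected regions the changes compose multiplicatively, so for a
chain A-B-C with signs (+, -) the implied A-C change is negative.  A
candidate simplified network *satisfies* an observed change when the sign
it implies for that pair (direct edge sign, or the sign propagated over
shortest tract paths) equals the observed sign; disagreement between
distinct shortest paths is indeterminate and counts as a violation.

``search_max_consistent`` automates the search for the simplified network
that satisfies the largest fraction of observed changes, exhaustively for
small cores and by seeded hill-climbing with restarts otherwise.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import yaml

from .graph_metrics import BrainNetwork, betweenness_centrality
from .literature_model import ConnectivityChangeRecord, RecordSet, qualitative_direction
from .reduction_pipeline import network_signature

logger = logging.getLogger(__name__)

INDETERMINATE = 0  # sentinel returned when shortest paths disagree / no path


class TractConsistencyError(ValueError):
    pass


@dataclass(frozen=True)
class TractMap:
    """Declared anatomical adjacency: unordered region pairs with a direct
    fiber connection.  Symmetric, no self-pairs."""

    adjacency: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        canon = set()
        for a, b in self.adjacency:
            if a == b:
                raise TractConsistencyError(f"self-pair ({a}, {b}) in tract map")
            canon.add((min(a, b), max(a, b)))
        object.__setattr__(self, "adjacency", frozenset(canon))

    @property
    def regions(self) -> set[str]:
        return {r for pair in self.adjacency for r in pair}

    @classmethod
    def from_pairs(cls, pairs: Iterable[Sequence[str]]) -> "TractMap":
        return cls(adjacency=frozenset((p[0], p[1]) for p in pairs))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TractMap":
        """Load from YAML with a ``tracts: [[A, B], ...]`` list."""
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_pairs(payload.get("tracts", []))

    def to_yaml(self, path: str | Path) -> None:
        pairs = sorted([list(p) for p in self.adjacency])
        with open(path, "w") as fh:
            yaml.safe_dump({"tracts": pairs}, fh)


class SignedCoreNetwork:
    """A tract-admissible signed network over the core regions.

    Every edge is a tract-map edge (when a map is supplied) and carries a
    sign; isolated core regions are retained as nodes so implied signs for
    their pairs evaluate to indeterminate rather than erroring.
    """

    def __init__(
        self,
        nodes: Iterable[str],
        edge_signs: Mapping[tuple[str, str], int],
        tract_map: TractMap | None = None,
    ) -> None:
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for (a, b), s in edge_signs.items():
            if a == b:
                raise TractConsistencyError(f"self-pair edge ({a}, {b})")
            if s not in (1, -1):
                raise TractConsistencyError(f"edge ({a}, {b}) sign must be ±1, got {s}")
            if tract_map is not None and (min(a, b), max(a, b)) not in tract_map.adjacency:
                raise TractConsistencyError(
                    f"edge ({a}, {b}) is not a declared tract"
                )
            if a not in g or b not in g:
                raise TractConsistencyError(f"edge ({a}, {b}) endpoint outside node set")
            g.add_edge(a, b, sign=int(s))
        self.graph = g

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {(min(u, v), max(u, v)) for u, v in self.graph.edges}

    @property
    def edge_sign(self) -> dict[tuple[str, str], int]:
        return {
            (min(u, v), max(u, v)): d["sign"]
            for u, v, d in self.graph.edges(data=True)
        }

    def as_brain_network(self) -> BrainNetwork:
        return BrainNetwork(self.graph.copy())

    def __repr__(self) -> str:
        return (
            f"SignedCoreNetwork(nodes={sorted(self.nodes)}, "
            f"edges={sorted(self.edge_sign.items())})"
        )


@dataclass(frozen=True)
class ObservedChange:
    """One evaluated observation: pair, observed sign, implied sign."""

    pair: tuple[str, str]
    observed: int
    implied: int | None  # None = indeterminate


@dataclass(frozen=True)
class ConsistencyReport:
    """Which observed signed changes a candidate network satisfies.

    ``fraction`` is over the evaluated (post-exclusion) changes;
    ``fraction_pre_exclusion`` additionally counts conflict-excluded
    changes in the denominator, treating them as satisfied by exclusion —
    the headline convention when conflicting study conclusions are removed
    before the analysis.
    """

    satisfied: tuple[ObservedChange, ...]
    violated: tuple[ObservedChange, ...]
    fraction: float
    n_excluded_conflicts: int = 0
    mean_cb: dict[str, float] | None = None

    @property
    def n_evaluated(self) -> int:
        return len(self.satisfied) + len(self.violated)

    @property
    def fraction_pre_exclusion(self) -> float:
        total = self.n_evaluated + self.n_excluded_conflicts
        if total == 0:
            return 0.0
        return (len(self.satisfied) + self.n_excluded_conflicts) / total


def propagate_sign(path: Sequence[str], network: SignedCoreNetwork) -> int:
    """Sign implied along an ordered region chain: the product of edge signs."""
    if len(path) < 3:
        raise TractConsistencyError("path must span at least 2 edges")
    sign = 1
    for a, b in zip(path, path[1:]):
        if not network.graph.has_edge(a, b):
            raise TractConsistencyError(f"path step ({a}, {b}) is not an edge")
        sign *= network.graph.edges[a, b]["sign"]
    return sign


def implied_sign(pair: Sequence[str], network: SignedCoreNetwork) -> int | None:
    """Sign the network implies for a region pair.

    Direct edges return their own sign.  Otherwise the sign is propagated
    over every shortest tract path; if distinct shortest paths disagree, or
    the pair is disconnected, the result is indeterminate (``None``).
    """
    a, b = pair
    for r in (a, b):
        if r not in network.graph:
            raise TractConsistencyError(f"region {r!r} not in network")
    if network.graph.has_edge(a, b):
        return network.graph.edges[a, b]["sign"]
    try:
        paths = nx.all_shortest_paths(network.graph, a, b)
        signs = {propagate_sign(p, network) for p in paths}
    except nx.NetworkXNoPath:
        return None
    return signs.pop() if len(signs) == 1 else None


def _observed_pairs(
    observed: RecordSet | Iterable[ConnectivityChangeRecord],
) -> list[tuple[tuple[str, str], int]]:
    """Collapse records to unique (pair, sign); conflicting pairs must have
    been excluded upstream."""
    signs: dict[tuple[str, str], int] = {}
    for rec in observed:
        s = qualitative_direction(rec)
        if signs.get(rec.pair, s) != s:
            raise TractConsistencyError(
                f"conflicting observed signs for {rec.pair}; run conflict "
                "resolution before the consistency analysis"
            )
        signs[rec.pair] = s
    return sorted(signs.items())


def consistency_report(
    network: SignedCoreNetwork,
    observed: RecordSet | Iterable[ConnectivityChangeRecord],
    n_excluded_conflicts: int = 0,
) -> ConsistencyReport:
    """Score every observed signed change against the network's implied signs.

    A change is satisfied iff the implied sign equals the observed one;
    indeterminate implications count as violations.  Observed pairs with an
    endpoint outside the network's node set raise.
    """
    satisfied: list[ObservedChange] = []
    violated: list[ObservedChange] = []
    for pair, obs_sign in _observed_pairs(observed):
        for r in pair:
            if r not in network.graph:
                raise TractConsistencyError(
                    f"observed pair {pair} has endpoint {r!r} outside the core"
                )
        imp = implied_sign(pair, network)
        change = ObservedChange(pair=pair, observed=obs_sign, implied=imp)
        (satisfied if imp == obs_sign else violated).append(change)
    n_eval = len(satisfied) + len(violated)
    return ConsistencyReport(
        satisfied=tuple(satisfied),
        violated=tuple(violated),
        fraction=len(satisfied) / n_eval if n_eval else 0.0,
        n_excluded_conflicts=n_excluded_conflicts,
    )


def _connected_on_support(nodes: set[str], edges: Iterable[tuple[str, str]]) -> bool:
    g = nx.Graph()
    g.add_edges_from(edges)
    return g.number_of_nodes() > 0 and nx.is_connected(g)


def _candidate(
    all_nodes: set[str], edge_signs: dict[tuple[str, str], int]
) -> SignedCoreNetwork:
    return SignedCoreNetwork(nodes=all_nodes, edge_signs=edge_signs)


def search_max_consistent(
    tracts: TractMap,
    observed: RecordSet | Iterable[ConnectivityChangeRecord],
    mode: str = "auto",
    seed: int = 0,
    n_restarts: int = 20,
    n_excluded_conflicts: int = 0,
    max_exhaustive_edges: int = 16,
) -> tuple[SignedCoreNetwork, ConsistencyReport]:
    """Find the tract-admissible signed network maximising consistency.

    Candidates are connected edge subsets of the tract map; edges whose
    pair is directly observed carry the observed sign, other edges range
    over both signs.  Ties break toward fewer edges, then lexicographically
    smallest signature.  ``exhaustive`` mode enumerates all candidates
    (guarded by ``max_exhaustive_edges``); ``greedy`` hill-climbs with
    seeded restarts; ``auto`` picks exhaustive when feasible.
    """
    obs = _observed_pairs(observed)
    tract_edges = sorted(tracts.adjacency)
    if not tract_edges:
        raise TractConsistencyError("tract map has no edges")
    all_nodes = tracts.regions | {r for pair, _ in obs for r in pair}
    observed_signs = dict(obs)

    if mode == "auto":
        mode = "exhaustive" if len(tract_edges) <= max_exhaustive_edges else "greedy"
    if mode == "exhaustive" and len(tract_edges) > max_exhaustive_edges:
        raise TractConsistencyError(
            f"{len(tract_edges)} tract edges exceed the exhaustive-search "
            f"guard ({max_exhaustive_edges}); use greedy mode"
        )

    def score(edge_signs: dict[tuple[str, str], int]):
        net = _candidate(all_nodes, edge_signs)
        rep = consistency_report(
            net, _obs_as_records(obs), n_excluded_conflicts=n_excluded_conflicts
        )
        return net, rep

    if mode == "exhaustive":
        best = None  # ((-fraction, n_edges, signature), net, report)
        for k in range(1, len(tract_edges) + 1):
            for subset in itertools.combinations(tract_edges, k):
                if not _connected_on_support(all_nodes, subset):
                    continue
                free = [e for e in subset if e not in observed_signs]
                for flips in itertools.product((1, -1), repeat=len(free)):
                    edge_signs = {
                        e: observed_signs.get(e, 1) for e in subset
                    }
                    edge_signs.update(dict(zip(free, flips)))
                    net, rep = score(edge_signs)
                    key = (
                        -rep.fraction,
                        len(subset),
                        network_signature(net.as_brain_network()),
                        tuple(sorted(edge_signs.items())),
                    )
                    if best is None or key < best[0]:
                        best = (key, net, rep)
            # smaller subsets already enumerated; nothing larger can beat 1.0
            if best is not None and best[2].fraction == 1.0:
                break
        if best is None:
            raise TractConsistencyError("no connected candidate network exists")
        return best[1], best[2]

    if mode != "greedy":
        raise ValueError(f"unknown search mode {mode!r}")

    # Greedy hill-climbing: toggle edges in/out and flip free-edge signs,
    # accepting strict improvements, with seeded restarts.
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        included = {e: bool(rng.integers(2)) for e in tract_edges}
        free_sign = {
            e: int(rng.choice([1, -1]))
            for e in tract_edges
            if e not in observed_signs
        }
        if not any(included.values()):
            included[tract_edges[int(rng.integers(len(tract_edges)))]] = True

        def current():
            edge_signs = {
                e: observed_signs.get(e, free_sign.get(e, 1))
                for e, inc in included.items()
                if inc
            }
            if not edge_signs or not _connected_on_support(all_nodes, edge_signs):
                return None
            return score(edge_signs)

        state = current()
        improved = True
        while improved:
            improved = False
            for e in tract_edges:
                included[e] = not included[e]
                trial = current()
                if trial is not None and (
                    state is None or trial[1].fraction > state[1].fraction
                ):
                    state, improved = trial, True
                else:
                    included[e] = not included[e]
            for e in list(free_sign):
                free_sign[e] = -free_sign[e]
                trial = current()
                if trial is not None and (
                    state is None or trial[1].fraction > state[1].fraction
                ):
                    state, improved = trial, True
                else:
                    free_sign[e] = -free_sign[e]
        if state is not None:
            key = (
                -state[1].fraction,
                len(state[0].edges),
                network_signature(state[0].as_brain_network()),
            )
            if best is None or key < best[0]:
                best = (key, state[0], state[1])
    if best is None:
        raise TractConsistencyError("no connected candidate network found")
    return best[1], best[2]


def _obs_as_records(
    obs: list[tuple[tuple[str, str], int]]
) -> list[ConnectivityChangeRecord]:
    return [
        ConnectivityChangeRecord(
            study_id=f"obs{i}",
            modality="MRI",
            indicator="FC",
            region_a=a,
            region_b=b,
            direction=s,
        )
        for i, ((a, b), s) in enumerate(obs)
    ]


def mean_core_betweenness(
    modes: Sequence[SignedCoreNetwork | BrainNetwork],
) -> dict[str, float]:
    """Arithmetic mean of normalised betweenness per region across network
    modes sharing a common node set."""
    if not modes:
        raise TractConsistencyError("no network modes given")
    nets = [
        m.as_brain_network() if isinstance(m, SignedCoreNetwork) else m
        for m in modes
    ]
    node_set = nets[0].nodes
    for net in nets[1:]:
        if net.nodes != node_set:
            raise TractConsistencyError(
                f"node-set mismatch across modes: {sorted(node_set)} vs "
                f"{sorted(net.nodes)}"
            )
    totals = {n: 0.0 for n in node_set}
    for net in nets:
        cb = betweenness_centrality(net, normalized=True)
        for n in node_set:
            totals[n] += cb[n]
    return {n: t / len(nets) for n, t in totals.items()}
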