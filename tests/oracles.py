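"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the library code paths they check: betweenness is
recomputed by explicit enumeration of every shortest path from BFS
predecessor DAGs, and the maximally consistent signed network is found by
raw enumeration of every edge subset and sign assignment.
"""

from __future__ import annotations

import itertools
from collections import deque


def _bfs_dag(adj: dict, src):
    """BFS distances and shortest-path predecessor lists from src."""
    dist = {src: 0}
    preds: dict = {src: []}
    q = deque([src])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                preds[v] = [u]
                q.append(v)
            elif dist[v] == dist[u] + 1:
                preds[v].append(u)
    return dist, preds


def _all_paths(preds: dict, src, dst):
    """Enumerate every shortest path src -> dst from the predecessor DAG."""
    if dst not in preds:
        return
    stack = [(dst, [dst])]
    while stack:
        node, path = stack.pop()
        if node == src:
            yield path[::-1]
            continue
        for p in preds[node]:
            stack.append((p, path + [p]))


def brute_betweenness(edges, nodes=None, normalized=True):
    """Fractional betweenness by explicit shortest-path enumeration."""
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    all_nodes = set(adj)
    if nodes is not None:
        all_nodes |= set(nodes)
        for n in all_nodes:
            adj.setdefault(n, set())
    cb = {n: 0.0 for n in all_nodes}
    node_list = sorted(all_nodes, key=str)
    for i, j in itertools.combinations(node_list, 2):
        _, preds = _bfs_dag(adj, i)
        paths = list(_all_paths(preds, i, j))
        if not paths:
            continue
        for path in paths:
            for mid in path[1:-1]:
                cb[mid] += 1.0 / len(paths)
    g = len(all_nodes)
    if normalized and g > 2:
        scale = 2.0 / ((g - 1) * (g - 2))
        cb = {n: v * scale for n, v in cb.items()}
    return cb


def brute_implied_sign(edge_signs: dict, pair) -> int | None:
    """Implied sign over shortest paths, by raw enumeration; None when
    indeterminate or disconnected."""
    adj: dict = {}
    for u, v in edge_signs:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    a, b = pair
    if a not in adj or b not in adj:
        return None
    key = (min(a, b), max(a, b))
    if key in {(min(u, v), max(u, v)) for u, v in edge_signs}:
        canon = {(min(u, v), max(u, v)): s for (u, v), s in edge_signs.items()}
        return canon[key]
    _, preds = _bfs_dag(adj, a)
    signs = set()
    canon = {(min(u, v), max(u, v)): s for (u, v), s in edge_signs.items()}
    for path in _all_paths(preds, a, b):
        s = 1
        for u, v in zip(path, path[1:]):
            s *= canon[(min(u, v), max(u, v))]
        signs.add(s)
    if not signs or len(signs) > 1:
        return None
    return signs.pop()


def brute_max_consistent_fraction(tract_edges, observed: dict) -> float:
    """Best achievable consistency fraction over *all* connected edge
    subsets of the tract map and all sign assignments consistent with the
    directly observed edge signs."""
    tract_edges = [tuple(sorted(e)) for e in tract_edges]
    observed = {tuple(sorted(p)): s for p, s in observed.items()}
    best = 0.0
    for k in range(1, len(tract_edges) + 1):
        for subset in itertools.combinations(tract_edges, k):
            # connectivity over incident nodes
            nodes = {n for e in subset for n in e}
            adj: dict = {n: set() for n in nodes}
            for u, v in subset:
                adj[u].add(v)
                adj[v].add(u)
            seen = set()
            stack = [next(iter(nodes))]
            while stack:
                n = stack.pop()
                if n in seen:
                    continue
                seen.add(n)
                stack.extend(adj[n])
            if seen != nodes:
                continue
            free = [e for e in subset if e not in observed]
            for assignment in itertools.product((1, -1), repeat=len(free)):
                edge_signs = {e: observed[e] for e in subset if e in observed}
                edge_signs.update(dict(zip(free, assignment)))
                n_sat = sum(
                    1
                    for pair, s in observed.items()
                    if brute_implied_sign(edge_signs, pair) == s
                )
                best = max(best, n_sat / len(observed))
    return best
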