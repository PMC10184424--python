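"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the definitions with naive data structures
(explicit breadth-first search, factorial arithmetic, exhaustive subset
enumeration) and deliberately shares no code with the package.
"""

from __future__ import annotations

import itertools
import math
from collections import deque
from fractions import Fraction


def bfs_distances(adj: dict, source, cutoff=None) -> dict:
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        if cutoff is not None and dist[u] >= cutoff:
            continue
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def novel_score(adj: dict, weights: dict, alpha: float, max_depth: int) -> dict:
    n = len(adj)
    out = {}
    for v in adj:
        deg = len(adj[v])
        if deg == 0 or n == 1:
            out[v] = 0.0
            continue
        dist = bfs_distances(adj, v, cutoff=max_depth)
        infl = sum(weights[u] * alpha ** d for u, d in dist.items() if u != v)
        out[v] = (deg / (n - 1)) * infl
    return out


def degree(adj):
    return {v: float(len(adj[v])) for v in adj}


def _components(adj):
    seen = set()
    for v in adj:
        if v in seen:
            continue
        comp = set(bfs_distances(adj, v))
        seen |= comp
        yield comp


def closeness(adj):
    out = {}
    for comp in _components(adj):
        for v in comp:
            if len(comp) == 1:
                out[v] = 0.0
            else:
                dist = bfs_distances(adj, v)
                out[v] = (len(comp) - 1) / sum(dist.values())
    return out


def radiality(adj):
    out = {}
    for comp in _components(adj):
        if len(comp) == 1:
            out.update({v: 0.0 for v in comp})
            continue
        dists = {v: bfs_distances(adj, v) for v in comp}
        diam = max(max(d.values()) for d in dists.values())
        for v in comp:
            out[v] = sum(diam + 1 - d for u, d in dists[v].items() if u != v) / (len(comp) - 1)
    return out


def avg_shortest_path(adj):
    out = {}
    for comp in _components(adj):
        for v in comp:
            if len(comp) == 1:
                out[v] = math.inf
            else:
                out[v] = sum(bfs_distances(adj, v).values()) / (len(comp) - 1)
    return out


def clustering(adj):
    out = {}
    for v in adj:
        nbrs = list(adj[v])
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if b in adj[a]
        )
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def neighborhood_connectivity(adj):
    return {
        v: (sum(len(adj[u]) for u in adj[v]) / len(adj[v])) if adj[v] else 0.0 for v in adj
    }


CENTRALITY_ORACLES = {
    "degree": degree,
    "closeness": closeness,
    "radiality": radiality,
    "clustering_coefficient": clustering,
    "neighborhood_connectivity": neighborhood_connectivity,
    "avg_shortest_path": avg_shortest_path,
}


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> Fraction:
    """P(X >= k) by direct enumeration of the probability mass function."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for x in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, x) * math.comb(N - K, n - x), denom)
    return total


def best_coverage_of_size(sets: dict, universe: set, size: int) -> int:
    """Exhaustive maximum number of universe elements covered by any `size` sets."""
    best = 0
    for combo in itertools.combinations(sorted(sets), size):
        covered = set().union(*(sets[c] for c in combo)) & universe
        best = max(best, len(covered))
    return best
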