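"""Node-importance scoring and median-threshold key-network extraction.

The headline scorer combines two ingredients:

* the *connection probability* ``p(v) = deg(v) / (N - 1)`` — how likely the
  node is to touch another node of the network at all, and
* the *influence* ``I(v) = sum over u != v, d(v,u) <= max_depth of
  w(u) * alpha ** d(v,u)`` — a damped sum of the weights of all nodes within
  ``max_depth`` hops, where pathogenic genes carry weight
  ``1 + ln(1 + n_publications)`` and every other node weight 1.

``score(v) = p(v) * I(v)``.  High scores therefore need both broad direct
connectivity and proximity to heavily evidenced disease genes; an isolated
node scores exactly 0.  The scorer is exposed behind the same pluggable
interface as the six classical centralities so alternative formulations can
be swapped in without touching downstream selection.

Key-network extraction keeps the nodes whose score strictly exceeds the
median over *all* nodes of the network (layers pooled), together with the
edges among them.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Callable

import networkx as nx
import numpy as np

from .network import CTPNetwork

logger = logging.getLogger(__name__)

IMPORTANCE_METHODS = (
    "novel",
    "degree",
    "closeness",
    "radiality",
    "clustering_coefficient",
    "neighborhood_connectivity",
    "avg_shortest_path",
)

#: methods where a *smaller* value means a more central node; their scores
#: are negated before median thresholding so "key" always means "central"
INVERTED_METHODS = frozenset({"avg_shortest_path"})


def novel_importance(
    net: CTPNetwork, alpha: float = 0.5, max_depth: int = 3
) -> dict[str, float]:
    """Damped weight-propagating influence times connection probability.

    ``alpha`` in (0, 1) is the per-hop damping factor; ``max_depth`` bounds
    the breadth-first propagation (and the all-pairs cost on large graphs).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if max_depth < 1:
        raise ValueError(f"max_depth must be >= 1, got {max_depth}")
    g = net.graph
    n = g.number_of_nodes()
    if n == 0:
        return {}
    w = {v: d["weight"] for v, d in g.nodes(data=True)}
    damp = [alpha**d for d in range(max_depth + 1)]
    scores: dict[str, float] = {}
    for v in g.nodes:
        deg = g.degree(v)
        if deg == 0 or n == 1:
            scores[v] = 0.0
            continue
        p = deg / (n - 1)
        dist = nx.single_source_shortest_path_length(g, v, cutoff=max_depth)
        influence = sum(w[u] * damp[d] for u, d in dist.items() if u != v)
        scores[v] = p * influence
    return scores


# ---------------------------------------------------------------------------
# classical baselines
# ---------------------------------------------------------------------------


def _per_component_distance_scores(
    g: nx.Graph, reducer: Callable[[dict[str, int], int, int], float]
) -> dict[str, float]:
    """Apply ``reducer(dist_map, n_comp, diameter)`` node-wise per connected component."""
    scores: dict[str, float] = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        nc = len(comp)
        if nc == 1:
            (v,) = comp
            scores[v] = reducer({v: 0}, 1, 0)
            continue
        all_dist = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max(max(d.values()) for d in all_dist.values())
        for v in comp:
            scores[v] = reducer(all_dist[v], nc, diam)
    return scores


def _closeness(dist: dict[str, int], nc: int, _diam: int) -> float:
    if nc == 1:
        return 0.0
    return (nc - 1) / sum(dist.values())


def _radiality(dist: dict[str, int], nc: int, diam: int) -> float:
    if nc == 1:
        return 0.0
    return sum(diam + 1 - d for u, d in dist.items() if d > 0) / (nc - 1)


def _avg_shortest_path(dist: dict[str, int], nc: int, _diam: int) -> float:
    # an isolated node reaches nobody: infinitely peripheral, never "key"
    if nc == 1:
        return math.inf
    return sum(dist.values()) / (nc - 1)


def baseline_centrality(net: CTPNetwork, method: str) -> dict[str, float]:
    """One of the six classical centralities, per the standard definitions.

    Distance-based scores (closeness, radiality, average shortest path) are
    computed per connected component with ``n`` the component size.
    """
    g = net.graph
    if method == "degree":
        return {v: float(d) for v, d in g.degree()}
    if method == "closeness":
        return _per_component_distance_scores(g, _closeness)
    if method == "radiality":
        return _per_component_distance_scores(g, _radiality)
    if method == "clustering_coefficient":
        return {v: float(c) for v, c in nx.clustering(g).items()}
    if method == "neighborhood_connectivity":
        deg = dict(g.degree())
        return {
            v: (sum(deg[u] for u in g.neighbors(v)) / deg[v]) if deg[v] else 0.0
            for v in g.nodes
        }
    if method == "avg_shortest_path":
        return _per_component_distance_scores(g, _avg_shortest_path)
    raise ValueError(
        f"unknown centrality method {method!r}; expected one of "
        f"{', '.join(m for m in IMPORTANCE_METHODS if m != 'novel')}"
    )


def score_nodes(
    net: CTPNetwork,
    method: str = "novel",
    alpha: float = 0.5,
    max_depth: int = 3,
) -> dict[str, float]:
    """Dispatch to the headline scorer or one of the six baselines."""
    if method == "novel":
        return novel_importance(net, alpha=alpha, max_depth=max_depth)
    if method not in IMPORTANCE_METHODS:
        raise ValueError(
            f"unknown method {method!r}; expected one of {', '.join(IMPORTANCE_METHODS)}"
        )
    return baseline_centrality(net, method)


# ---------------------------------------------------------------------------
# key-network extraction
# ---------------------------------------------------------------------------


@dataclass
class ImportanceResult:
    """Per-node scores for one method and the derived key functional network."""

    method: str
    scores: dict[str, float]
    median: float
    key_nodes: set[str]
    key_network: CTPNetwork

    def key_genes(self) -> set[str]:
        """Gene symbols (non-component nodes) of the key network."""
        return self.key_network.noncomponent_nodes


def extract_key_network(
    net: CTPNetwork, scores: dict[str, float], method: str = "novel"
) -> ImportanceResult:
    """Keep nodes scoring strictly above the network-wide median.

    The median is taken over all nodes jointly (not per layer).  For methods
    where small values are central (average shortest path length) the scores
    are negated first, so "above the median" uniformly means "more central".
    Retained nodes that end up isolated in the induced subgraph are kept and
    logged.  If every node scores identically the key set is empty and a
    warning is emitted.
    """
    missing = set(net.graph.nodes) - set(scores)
    if missing:
        raise ValueError(f"scores missing for {len(missing)} node(s), e.g. {sorted(missing)[:3]}")
    oriented = scores
    if method in INVERTED_METHODS:
        oriented = {v: -s for v, s in scores.items()}
    vals = np.asarray([oriented[v] for v in net.graph.nodes], dtype=float)
    med = float(np.median(vals[np.isfinite(vals)])) if np.isfinite(vals).any() else 0.0
    key = {v for v in net.graph.nodes if oriented[v] > med}
    if not key:
        warnings.warn(
            f"all {method} scores are at or below the median ({med!r}); key network is empty",
            stacklevel=2,
        )
    sub = net.induced_subgraph(key)
    n_isolated = sum(1 for v in key if sub.graph.degree(v) == 0)
    if n_isolated:
        logger.info(
            "extract_key_network[%s]: %d retained node(s) are isolated in the key network",
            method,
            n_isolated,
        )
    return ImportanceResult(
        method=method, scores=dict(scores), median=med, key_nodes=key, key_network=sub
    )
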