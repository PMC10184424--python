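"""Contribution Decision Rate: greedy coverage ranking of components.

Given the key functional network, each component's value is what it adds to
the coverage of the *coverage universe*.  By default the universe is the set
of non-component key-network nodes adjacent to at least one component there
(the node-coverage reading; with it, selecting every component always reaches
coverage 1).  Two alternative universes are available: ``all`` (every
non-component key node, so nodes no component touches are permanently
uncovered) and ``edges`` (key-network edges, covered when incident to a
selected component or to one of its neighbours).

Ranking is the classical greedy maximum-coverage order: repeatedly pick the
component with the largest marginal gain, breaking ties by higher
key-network degree and then lexicographic id.  The marginal gain of a
component at its selection step is its CDR.  The key functional components
(KFC) are the shortest ranking prefix whose cumulative coverage reaches the
threshold (default 90%).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

from .network import CTPNetwork

logger = logging.getLogger(__name__)

UNIVERSE_MODES = ("adjacent", "all", "edges")


@dataclass(frozen=True)
class CDREntry:
    component_id: str
    gain: int  # newly covered universe elements at this step
    marginal: float  # gain / |universe|  (this component's CDR)
    cumulative: float


@dataclass
class CDRRanking:
    entries: list[CDREntry]
    coverage_universe: frozenset
    universe_mode: str = "adjacent"
    kfc_threshold: Optional[float] = None

    @property
    def order(self) -> list[str]:
        return [e.component_id for e in self.entries]

    def cumulative_at(self, k: int) -> float:
        if k <= 0:
            return 0.0
        return self.entries[min(k, len(self.entries)) - 1].cumulative


def _universe(key_net: CTPNetwork, mode: str) -> frozenset:
    comps = key_net.components
    g = key_net.graph
    if mode == "adjacent":
        return frozenset(
            v for v in key_net.noncomponent_nodes if any(u in comps for u in g.neighbors(v))
        )
    if mode == "all":
        return frozenset(key_net.noncomponent_nodes)
    if mode == "edges":
        return frozenset(frozenset(e) for e in g.edges)
    raise ValueError(f"unknown universe mode {mode!r}; expected one of {UNIVERSE_MODES}")


def _covered_by(component: str, key_net: CTPNetwork, universe: frozenset, mode: str) -> set:
    g = key_net.graph
    nbrs = set(g.neighbors(component))
    if mode in ("adjacent", "all"):
        return nbrs & universe
    reach = nbrs | {component}
    return {e for e in universe if e & reach}


def coverage(
    S: Iterable[str],
    key_net: CTPNetwork,
    universe_mode: str = "adjacent",
) -> float:
    """Fraction of the coverage universe reached by the component set ``S``."""
    comps = key_net.components
    if not comps:
        raise ValueError("key network contains no component nodes")
    S = set(S)
    unknown = S - comps
    if unknown:
        raise ValueError(f"unknown component id(s): {sorted(unknown)}")
    universe = _universe(key_net, universe_mode)
    if not universe:
        return 0.0
    covered: set = set()
    for c in S:
        covered |= _covered_by(c, key_net, universe, universe_mode)
    return len(covered) / len(universe)


def rank_cdr(
    key_net: CTPNetwork,
    universe_mode: str = "adjacent",
    static: bool = False,
) -> CDRRanking:
    """Greedy maximum-coverage ranking of the key network's components.

    With ``static=True`` components are instead sorted once by their
    individual coverage (no marginal re-evaluation); marginal and cumulative
    values are then accounted along that fixed order.
    """
    comps = sorted(key_net.components)
    if not comps:
        raise ValueError("key network contains no component nodes")
    universe = _universe(key_net, universe_mode)
    sets = {c: _covered_by(c, key_net, universe, universe_mode) for c in comps}
    deg = dict(key_net.graph.degree())

    def tiebreak(c: str) -> tuple:
        return (-deg[c], c)

    n_u = len(universe)
    entries: list[CDREntry] = []
    covered: set = set()

    if static:
        order = sorted(comps, key=lambda c: (-len(sets[c]),) + tiebreak(c))
        for c in order:
            gain = len(sets[c] - covered)
            covered |= sets[c]
            entries.append(
                CDREntry(c, gain, gain / n_u if n_u else 0.0, len(covered) / n_u if n_u else 0.0)
            )
        return CDRRanking(entries, universe, universe_mode)

    remaining = set(comps)
    while remaining:
        best = min(
            remaining,
            key=lambda c: (-len(sets[c] - covered),) + tiebreak(c),
        )
        gain = len(sets[best] - covered)
        if gain == 0:
            break
        covered |= sets[best]
        remaining.discard(best)
        entries.append(CDREntry(best, gain, gain / n_u, len(covered) / n_u))
    # exhausted components contribute nothing: append in tie-break order
    final = len(covered) / n_u if n_u else 0.0
    for c in sorted(remaining, key=tiebreak):
        entries.append(CDREntry(c, 0, 0.0, final))
    logger.info(
        "rank_cdr: %d components over a universe of %d (%s mode), final coverage %.4f",
        len(comps),
        n_u,
        universe_mode,
        final,
    )
    return CDRRanking(entries, universe, universe_mode)


def select_kfc(ranking: CDRRanking, threshold: float = 0.90) -> list[str]:
    """Shortest ranking prefix whose cumulative coverage reaches ``threshold``.

    If the threshold is unreachable, returns the full positive-marginal
    prefix with a warning.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ranking.kfc_threshold = threshold
    for i, e in enumerate(ranking.entries):
        if e.cumulative >= threshold:
            return [x.component_id for x in ranking.entries[: i + 1]]
    positive = [e.component_id for e in ranking.entries if e.gain > 0]
    final = ranking.entries[-1].cumulative if ranking.entries else 0.0
    warnings.warn(
        f"coverage threshold {threshold:.2f} unreachable (max {final:.4f}); "
        f"returning the full positive-marginal prefix ({len(positive)} components)",
        stacklevel=2,
    )
    return positive
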