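"""Domain types and construction of the component-target-pathogenic (CTP) network.

The CTP network is an undirected graph with three node layers:

``component``
    a formula chemical (only ``ct`` edges allowed);
``target``
    a predicted protein target of at least one component;
``pathogenic``
    a disease gene carrying a publication-count-derived weight.

A protein may be both a predicted target and a pathogenic gene; such nodes
carry both layer labels.  Edges are typed ``ct`` (component-target) or ``pp``
(protein-protein).  All non-pathogenic nodes have weight 1; pathogenic nodes
have weight ``1 + ln(1 + n_publications)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

LAYERS = ("component", "target", "pathogenic", "linker")

CT_EDGE = "ct"
PP_EDGE = "pp"


@dataclass(frozen=True)
class ComponentRecord:
    """One herb chemical with its ADMET properties and herb memberships.

    Numeric ADMET fields are ``None`` when missing in the source table —
    never silently zero.  ``validated`` marks components experimentally
    confirmed at high concentration; they bypass ADMET screening.
    """

    component_id: str
    name: str
    herbs: frozenset[str]
    mw: Optional[float] = None
    logp: Optional[float] = None
    hbd: Optional[int] = None
    hba: Optional[int] = None
    rotatable_bonds: Optional[int] = None
    ob_percent: Optional[float] = None
    gi_class: str = "missing"  # {"high", "low", "missing"}
    validated: bool = False

    def __post_init__(self) -> None:
        if not self.component_id:
            raise ValueError("component_id must be non-empty")
        if not self.herbs:
            raise ValueError(f"component {self.component_id!r}: herbs must be non-empty")
        for fld in ("hbd", "hba", "rotatable_bonds"):
            v = getattr(self, fld)
            if v is not None and v < 0:
                raise ValueError(f"component {self.component_id!r}: {fld} must be >= 0, got {v}")
        if self.ob_percent is not None and not (0.0 <= self.ob_percent <= 100.0):
            raise ValueError(
                f"component {self.component_id!r}: ob_percent must be in [0, 100], "
                f"got {self.ob_percent}"
            )
        if self.gi_class not in ("high", "low", "missing"):
            raise ValueError(
                f"component {self.component_id!r}: gi_class must be high/low/missing, "
                f"got {self.gi_class!r}"
            )


@dataclass(frozen=True)
class PathogenicGene:
    """A disease-associated gene with its literature-evidence count."""

    symbol: str
    n_publications: int

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")
        if self.n_publications < 1:
            raise ValueError(
                f"gene {self.symbol}: n_publications must be >= 1, got {self.n_publications}"
            )

    @property
    def weight(self) -> float:
        return pathogenic_weight(self.n_publications)


def pathogenic_weight(n_publications: int) -> float:
    """Node weight from publication support: ``1 + ln(1 + n)``.

    The logarithm damps the heavy right tail of the publication-count
    distribution (most disease genes have a single supporting reference,
    a few have dozens) so that a single extensively studied gene cannot
    dominate the influence sums.
    """
    return 1.0 + math.log1p(float(n_publications))


class CTPNetwork:
    """The merged four-layer undirected graph.

    Thin wrapper over :class:`networkx.Graph` fixing the node/edge attribute
    schema: node attributes ``layers`` (frozenset of layer labels), ``weight``
    (float) and optionally ``n_publications``; edge attribute ``etype`` in
    ``{"ct", "pp"}`` and optionally ``score`` (preserved confidence from a
    PPI export; never used in computation).
    """

    def __init__(self, graph: Optional[nx.Graph] = None) -> None:
        self.graph: nx.Graph = graph if graph is not None else nx.Graph()

    # -- construction helpers -------------------------------------------------

    def add_node(
        self,
        node: str,
        layers: Iterable[str],
        weight: float = 1.0,
        n_publications: Optional[int] = None,
    ) -> None:
        layers = frozenset(layers)
        unknown = layers - set(LAYERS)
        if unknown:
            raise ValueError(f"unknown layer(s) {sorted(unknown)} for node {node!r}")
        if node in self.graph:
            layers = layers | self.graph.nodes[node]["layers"]
        attrs = {"layers": layers, "weight": float(weight)}
        if n_publications is not None:
            attrs["n_publications"] = int(n_publications)
        self.graph.add_node(node, **attrs)

    def add_edge(self, u: str, v: str, etype: str, score: Optional[float] = None) -> None:
        if u == v:
            raise ValueError(f"self-loop on {u!r} not allowed")
        if etype not in (CT_EDGE, PP_EDGE):
            raise ValueError(f"unknown edge type {etype!r}")
        if u not in self.graph or v not in self.graph:
            missing = [x for x in (u, v) if x not in self.graph]
            raise ValueError(f"edge endpoints {missing} not in network")
        attrs = {"etype": etype}
        if score is not None:
            attrs["score"] = float(score)
        self.graph.add_edge(u, v, **attrs)

    # -- queries --------------------------------------------------------------

    def layers_of(self, node: str) -> frozenset[str]:
        return self.graph.nodes[node]["layers"]

    def nodes_in_layer(self, layer: str) -> set[str]:
        if layer not in LAYERS:
            raise ValueError(f"unknown layer {layer!r}; expected one of {LAYERS}")
        return {n for n, d in self.graph.nodes(data=True) if layer in d["layers"]}

    @property
    def components(self) -> set[str]:
        return self.nodes_in_layer("component")

    @property
    def noncomponent_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if "component" not in d["layers"]}

    def node_weight(self, node: str) -> float:
        return self.graph.nodes[node]["weight"]

    @property
    def node_weights(self) -> dict[str, float]:
        return {n: d["weight"] for n, d in self.graph.nodes(data=True)}

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    # -- derived networks -----------------------------------------------------

    def induced_subgraph(self, nodes: Iterable[str]) -> "CTPNetwork":
        """Induced subgraph preserving all node and edge attributes."""
        return CTPNetwork(nx.Graph(self.graph.subgraph(nodes)))

    def copy(self) -> "CTPNetwork":
        return CTPNetwork(self.graph.copy())

    # -- equality / validation ------------------------------------------------

    def _node_table(self) -> dict:
        return {
            n: (d["layers"], d["weight"], d.get("n_publications"))
            for n, d in self.graph.nodes(data=True)
        }

    def _edge_table(self) -> dict:
        return {
            frozenset((u, v)): (d["etype"], d.get("score"))
            for u, v, d in self.graph.edges(data=True)
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CTPNetwork):
            return NotImplemented
        return self._node_table() == other._node_table() and self._edge_table() == other._edge_table()

    def __repr__(self) -> str:
        return f"CTPNetwork(nodes={self.n_nodes()}, edges={self.n_edges()})"

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation.

        Components may only participate in ``ct`` edges; ``ct`` edges join a
        component to a non-component; self-loops are impossible by
        construction in :class:`networkx.Graph` plus the ``add_edge`` guard.
        """
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            lu, lv = self.layers_of(u), self.layers_of(v)
            if d["etype"] == CT_EDGE:
                comp = ("component" in lu, "component" in lv)
                if comp != (True, False) and comp != (False, True):
                    raise ValueError(f"ct edge {u!r}-{v!r} must join component to non-component")
            else:
                if "component" in lu or "component" in lv:
                    raise ValueError(f"pp edge {u!r}-{v!r} touches a component node")


@dataclass
class LayerStats:
    """Degree statistics for one node layer.

    ``mean_degree`` is ``None`` (flagged undefined, not zero) when the layer
    is empty.
    """

    layer: str
    n_nodes: int
    mean_degree: Optional[float]


@dataclass
class NetworkStats:
    per_layer: dict[str, LayerStats]
    n_nodes: int
    n_edges: int


def build_ct_network(
    components: Sequence[ComponentRecord],
    ct_edges: Iterable[tuple[str, str]],
) -> CTPNetwork:
    """Build the bipartite component-target (CT) layer.

    Duplicate edges (e.g. the same pair from several target predictors)
    collapse to a single unweighted edge.  Targets with no edge are absent;
    components with no edge are likewise dropped (with a logged count), so
    node totals equal the unique endpoints of the de-duplicated edge list.
    Target symbols are upper-cased once at ingest.

    Raises
    ------
    ValueError
        If an edge references an unknown component id, or a target symbol
        collides with a component id.
    """
    known = {c.component_id for c in components}
    net = CTPNetwork()
    pairs: set[tuple[str, str]] = set()
    for cid, target in ct_edges:
        if cid not in known:
            raise ValueError(f"ct edge references unknown component {cid!r}")
        tsym = target.strip().upper()
        if tsym in known:
            raise ValueError(
                f"target symbol {tsym!r} collides with a component id; "
                "component and protein namespaces must be disjoint"
            )
        pairs.add((cid, tsym))
    used_components = {cid for cid, _ in pairs}
    dropped = len(known - used_components)
    if dropped:
        logger.info("build_ct_network: %d component(s) without any ct edge dropped", dropped)
    for cid in sorted(used_components):
        net.add_node(cid, {"component"})
    for tsym in sorted({t for _, t in pairs}):
        net.add_node(tsym, {"target"})
    for cid, tsym in sorted(pairs):
        net.add_edge(cid, tsym, CT_EDGE)
    return net


def layer_degree_stats(net: CTPNetwork) -> NetworkStats:
    """Node count and mean degree per layer, plus global counts.

    Mean degree of a layer is the sum of that layer's node degrees divided by
    the layer's node count.  Nodes carrying two layer labels (target and
    pathogenic) contribute to both layers.  An empty layer is reported with
    count 0 and mean ``None``.
    """
    if net.n_nodes() == 0:
        raise ValueError("cannot compute degree statistics of an empty network")
    deg = dict(net.graph.degree())
    per_layer: dict[str, LayerStats] = {}
    for layer in LAYERS:
        members = net.nodes_in_layer(layer)
        if members:
            mean = sum(deg[n] for n in members) / len(members)
        else:
            mean = None
        per_layer[layer] = LayerStats(layer=layer, n_nodes=len(members), mean_degree=mean)
    return NetworkStats(per_layer=per_layer, n_nodes=net.n_nodes(), n_edges=net.n_edges())


def merge_ctp(
    ct: CTPNetwork,
    ppi_edges: Iterable[tuple],
    pathogenic: Sequence[PathogenicGene],
) -> CTPNetwork:
    """Merge the CT layer, a PPI edge list and the weighted pathogenic genes.

    Gene symbols are upper-cased once (the single documented normalization;
    matching is exact and case-sensitive thereafter).  PPI self-loops are
    dropped with a logged count; duplicate PPI pairs collapse (keeping the
    first confidence score seen, if any).  Proteins that appear only in the
    PPI list and are neither predicted targets nor pathogenic genes get the
    ``linker`` layer label.  Pathogenic genes without any edge are retained
    as isolated weighted nodes and logged: dropping them would silently
    shift the median used for key-network extraction.

    ``ppi_edges`` items are ``(a, b)`` or ``(a, b, score)``.
    """
    net = ct.copy()

    pgenes: dict[str, PathogenicGene] = {}
    for g in pathogenic:
        sym = g.symbol.strip().upper()
        if sym in pgenes:
            raise ValueError(f"duplicate pathogenic gene symbol {sym!r}")
        pgenes[sym] = g

    # de-duplicate PPI input, dropping self loops
    seen: dict[frozenset, Optional[float]] = {}
    n_self = 0
    for edge in ppi_edges:
        a, b = edge[0].strip().upper(), edge[1].strip().upper()
        score = float(edge[2]) if len(edge) > 2 and edge[2] is not None else None
        if a == b:
            n_self += 1
            continue
        key = frozenset((a, b))
        if key not in seen:
            seen[key] = score
    if n_self:
        logger.info("merge_ctp: dropped %d PPI self-loop(s)", n_self)

    components = net.components
    ppi_nodes = sorted({s for key in seen for s in key})
    for sym in ppi_nodes:
        if sym in components:
            raise ValueError(f"PPI symbol {sym!r} collides with a component id")
        if sym not in net.graph and sym not in pgenes:
            net.add_node(sym, {"linker"})

    # pathogenic annotation: add/extend nodes with weight and evidence count
    for sym in sorted(pgenes):
        g = pgenes[sym]
        if sym in components:
            raise ValueError(f"pathogenic gene {sym!r} collides with a component id")
        net.add_node(sym, {"pathogenic"}, weight=g.weight, n_publications=g.n_publications)
        # add_node unions layers but overwrites weight: reassert for overlap nodes
        net.graph.nodes[sym]["weight"] = g.weight
        net.graph.nodes[sym]["n_publications"] = g.n_publications

    for key in sorted(seen, key=sorted):
        a, b = sorted(key)
        net.add_edge(a, b, PP_EDGE, score=seen[key])

    isolated = [s for s in pgenes if net.graph.degree(s) == 0]
    if isolated:
        logger.info(
            "merge_ctp: %d pathogenic gene(s) have no edges; kept as isolated weighted nodes",
            len(isolated),
        )
    net.validate()
    return net
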