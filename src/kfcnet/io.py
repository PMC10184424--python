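"""Readers and writers for the delimited-text inputs and network files.

Tabular inputs (component table, edge lists, pathogenic-gene table) are
plain delimited text with a header row; the delimiter (tab, comma or
semicolon) is sniffed from the header.  Networks round-trip through three
formats:

``tsv``
    edge list ``source<TAB>target<TAB>edge_type[<TAB>score]`` preceded by
    ``#node`` comment lines carrying node layers/weights (so the round trip
    is lossless while remaining an ordinary edge list to other tools);
``sif``
    Cytoscape simple-interaction format with relation tokens ``ct``/``pp``,
    plus the same ``#node`` comment header;
``graphml``
    GraphML with node attributes ``layer`` (``|``-joined), ``weight`` and
    ``n_publications``, edge attributes ``etype`` and ``score``.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Optional, Union

import networkx as nx

from .network import CTPNetwork, ComponentRecord, PathogenicGene

logger = logging.getLogger(__name__)

NETWORK_FORMATS = ("tsv", "sif", "graphml")

_TRUE = {"true", "t", "yes", "y", "1"}
_FALSE = {"false", "f", "no", "n", "0", ""}
_MISSING = {"", "na", "nan", "none", "null", "-", "."}


def _sniff_delimiter(header_line: str) -> str:
    for delim in ("\t", ",", ";"):
        if delim in header_line:
            return delim
    return "\t"


def _open_table(path: Union[str, Path]):
    path = Path(path)
    fh = path.open(newline="")
    header = fh.readline()
    if not header:
        fh.close()
        raise ValueError(f"{path}: empty file (no header)")
    delim = _sniff_delimiter(header)
    fh.seek(0)
    return fh, csv.DictReader(fh, delimiter=delim)


def _parse_float(value: Optional[str], field: str, lineno: int) -> Optional[float]:
    if value is None or value.strip().lower() in _MISSING:
        return None
    try:
        return float(value)
    except ValueError:
        raise ValueError(f"line {lineno}: unparseable numeric value {value!r} for {field}") from None


def _parse_int(value: Optional[str], field: str, lineno: int) -> Optional[int]:
    f = _parse_float(value, field, lineno)
    if f is None:
        return None
    if f != int(f):
        raise ValueError(f"line {lineno}: expected integer for {field}, got {value!r}")
    return int(f)


def _parse_bool(value: Optional[str], field: str, lineno: int) -> bool:
    if value is None:
        return False
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"line {lineno}: unparseable boolean {value!r} for {field}")


def read_component_table(path: Union[str, Path]) -> list[ComponentRecord]:
    """Read the component table.

    Required columns: ``component_id``, ``name``, ``herbs`` (``;`` or ``|``
    separated).  Optional ADMET columns: ``mw``, ``logp``, ``hbd``, ``hba``,
    ``rotatable_bonds``, ``ob_percent``, ``gi_class``, ``validated``.
    Missing numeric values stay missing (``None``), never zero.

    Raises
    ------
    ValueError
        On a duplicate ``component_id`` (naming the id) or an unparseable
        numeric value (naming the line).
    """
    fh, reader = _open_table(path)
    try:
        if reader.fieldnames is None or "component_id" not in reader.fieldnames:
            raise ValueError(f"{path}: header must name a 'component_id' column")
        records: list[ComponentRecord] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            cid = (row.get("component_id") or "").strip()
            if not cid:
                raise ValueError(f"line {lineno}: empty component_id")
            if cid in seen:
                raise ValueError(f"duplicate component_id {cid!r}")
            seen.add(cid)
            herbs_raw = (row.get("herbs") or "").replace("|", ";")
            herbs = frozenset(h.strip() for h in herbs_raw.split(";") if h.strip())
            gi = (row.get("gi_class") or "missing").strip().lower() or "missing"
            if gi in _MISSING:
                gi = "missing"
            records.append(
                ComponentRecord(
                    component_id=cid,
                    name=(row.get("name") or cid).strip(),
                    herbs=herbs,
                    mw=_parse_float(row.get("mw"), "mw", lineno),
                    logp=_parse_float(row.get("logp"), "logp", lineno),
                    hbd=_parse_int(row.get("hbd"), "hbd", lineno),
                    hba=_parse_int(row.get("hba"), "hba", lineno),
                    rotatable_bonds=_parse_int(
                        row.get("rotatable_bonds"), "rotatable_bonds", lineno
                    ),
                    ob_percent=_parse_float(row.get("ob_percent"), "ob_percent", lineno),
                    gi_class=gi,
                    validated=_parse_bool(row.get("validated"), "validated", lineno),
                )
            )
        return records
    finally:
        fh.close()


def read_ct_edges(path: Union[str, Path]) -> list[tuple[str, str]]:
    """Read a component->target edge list (columns ``component_id``, ``target``)."""
    fh, reader = _open_table(path)
    try:
        edges = []
        for lineno, row in enumerate(reader, start=2):
            cid = (row.get("component_id") or "").strip()
            tgt = (row.get("target") or "").strip()
            if not cid or not tgt:
                raise ValueError(f"line {lineno}: ct edge needs component_id and target")
            edges.append((cid, tgt))
        return edges
    finally:
        fh.close()


def read_ppi_edges(path: Union[str, Path]) -> list[tuple]:
    """Read a PPI edge list (columns ``protein_a``, ``protein_b``[, ``score``])."""
    fh, reader = _open_table(path)
    try:
        edges: list[tuple] = []
        for lineno, row in enumerate(reader, start=2):
            a = (row.get("protein_a") or "").strip()
            b = (row.get("protein_b") or "").strip()
            if not a or not b:
                raise ValueError(f"line {lineno}: ppi edge needs protein_a and protein_b")
            score = _parse_float(row.get("score"), "score", lineno)
            edges.append((a, b) if score is None else (a, b, score))
        return edges
    finally:
        fh.close()


def read_pathogenic_table(path: Union[str, Path]) -> list[PathogenicGene]:
    """Read the pathogenic-gene table (columns ``symbol``, ``n_publications``)."""
    fh, reader = _open_table(path)
    try:
        genes = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            sym = (row.get("symbol") or "").strip()
            if not sym:
                raise ValueError(f"line {lineno}: empty gene symbol")
            if sym.upper() in seen:
                raise ValueError(f"duplicate pathogenic gene symbol {sym!r}")
            seen.add(sym.upper())
            npub = _parse_int(row.get("n_publications"), "n_publications", lineno)
            if npub is None:
                raise ValueError(f"line {lineno}: n_publications missing for {sym!r}")
            genes.append(PathogenicGene(symbol=sym, n_publications=npub))
        return genes
    finally:
        fh.close()


# ---------------------------------------------------------------------------
# network round-trip
# ---------------------------------------------------------------------------


def _node_header_lines(net: CTPNetwork) -> list[str]:
    lines = []
    for n in sorted(net.graph.nodes):
        d = net.graph.nodes[n]
        layers = "|".join(sorted(d["layers"]))
        npub = d.get("n_publications")
        lines.append(
            "#node\t%s\t%s\t%s\t%s" % (n, layers, repr(d["weight"]), "-" if npub is None else npub)
        )
    return lines


def _parse_node_header(line: str, net: CTPNetwork) -> None:
    parts = line.rstrip("\n").split("\t")
    if len(parts) != 5:
        raise ValueError(f"malformed #node line: {line!r}")
    _, node, layers, weight, npub = parts
    net.add_node(
        node,
        layers.split("|"),
        weight=float(weight),
        n_publications=None if npub == "-" else int(npub),
    )


def write_network(net: CTPNetwork, path: Union[str, Path], fmt: Optional[str] = None) -> None:
    """Write a network; format inferred from the extension when ``fmt`` is None."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {fmt!r}; supported: {', '.join(NETWORK_FORMATS)}")
    if fmt == "graphml":
        g = nx.Graph()
        for n in sorted(net.graph.nodes):
            d = net.graph.nodes[n]
            attrs = {"layer": "|".join(sorted(d["layers"])), "weight": float(d["weight"])}
            if d.get("n_publications") is not None:
                attrs["n_publications"] = int(d["n_publications"])
            g.add_node(n, **attrs)
        for u, v, d in net.graph.edges(data=True):
            attrs = {"etype": d["etype"]}
            if d.get("score") is not None:
                attrs["score"] = float(d["score"])
            g.add_edge(u, v, **attrs)
        nx.write_graphml(g, path)
        return
    sep = "\t" if fmt == "tsv" else " "
    with path.open("w") as fh:
        for line in _node_header_lines(net):
            fh.write(line + "\n")
        for u, v in sorted(map(lambda e: tuple(sorted(e)), net.graph.edges)):
            d = net.graph.edges[u, v]
            fields = [u, d["etype"], v] if fmt == "sif" else [u, v, d["etype"]]
            if d.get("score") is not None:
                if fmt == "sif":
                    fh.write("#edgescore\t%s\t%s\t%s\n" % (u, v, repr(d["score"])))
                else:
                    fields.append(repr(d["score"]))
            fh.write(sep.join(fields) + "\n")


def read_network(path: Union[str, Path], fmt: Optional[str] = None) -> CTPNetwork:
    """Read a network written by :func:`write_network` (lossless round trip)."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {fmt!r}; supported: {', '.join(NETWORK_FORMATS)}")
    net = CTPNetwork()
    if fmt == "graphml":
        g = nx.read_graphml(path)
        for n, d in g.nodes(data=True):
            net.add_node(
                n,
                d["layer"].split("|"),
                weight=float(d.get("weight", 1.0)),
                n_publications=d.get("n_publications"),
            )
        for u, v, d in g.edges(data=True):
            net.add_edge(u, v, d["etype"], score=d.get("score"))
        return net
    sep = "\t" if fmt == "tsv" else None  # SIF splits on any whitespace
    scores: dict[frozenset, float] = {}
    edge_lines: list[list[str]] = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#node\t"):
                _parse_node_header(line, net)
            elif line.startswith("#edgescore\t"):
                _, u, v, s = line.split("\t")
                scores[frozenset((u, v))] = float(s)
            elif line.startswith("#"):
                continue
            else:
                edge_lines.append(line.split(sep))
    for parts in edge_lines:
        if fmt == "sif":
            if len(parts) < 3:
                raise ValueError(f"malformed SIF line: {parts!r}")
            u, etype, v = parts[0], parts[1], parts[2]
            score = scores.get(frozenset((u, v)))
        else:
            if len(parts) < 2:
                raise ValueError(f"malformed edge line: {parts!r}")
            u, v = parts[0], parts[1]
            etype = parts[2] if len(parts) > 2 else "ct"
            score = float(parts[3]) if len(parts) > 3 else None
        # bare edge list without #node header: infer layers from the edge type
        if u not in net.graph:
            net.add_node(u, {"component"} if etype == "ct" else {"target"})
        if v not in net.graph:
            net.add_node(v, {"target"})
        net.add_edge(u, v, etype, score=score)
    return net
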