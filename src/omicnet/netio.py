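"""Readers and writers for network exchange formats.

GML and GraphML are the native formats: every attribute, including mapped
experiment data, survives a round trip verbatim.  SIF keeps only topology
and the interaction type.  SBML (Level 2/3 core) is read-only and expanded
into the bipartite species/process representation used throughout the
package: species become ``simple_chemical`` nodes, reactions become
``process`` nodes, and stoichiometric coefficients become edge weights.

The GML dialect of :mod:`networkx` restricts attribute keys to identifiers
and has no boolean type, so keys and booleans pass through a reversible
escaping layer (``vK``/``vB`` markers); GraphML needs none of this.
"""

from __future__ import annotations

import re
from pathlib import Path

import networkx as nx

from .graph import AttributedGraph, GraphStructureError

FORMATS = ("gml", "graphml", "sif", "sbml")

_SAFE_KEY = re.compile(r"^[A-Za-z][A-Za-z0-9]*$")
#: keys networkx/GML itself writes; user attributes of this name get escaped
_GML_RESERVED = {
    "label", "id", "source", "target", "key", "directed", "multigraph",
    "node", "edge", "graph", "name",
}
_STRUCT_NODE_ID = "vKnid"
_STRUCT_EDGE_ID = "vKeid"
_STRUCT_LEAF = "vKleaf"


class ParseError(ValueError):
    """Malformed input file; message names the file and offending element."""


class UnsupportedFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GML key/value escaping


def _esc(raw: str) -> str:
    out = []
    for c in raw:
        if c.isascii() and c.isalnum():
            out.append(c)
        else:
            out.append(f"_{ord(c):x}_")
    return "".join(out)


def _unesc(enc: str) -> str:
    out = []
    i = 0
    while i < len(enc):
        c = enc[i]
        if c == "_":
            j = enc.index("_", i + 1)
            out.append(chr(int(enc[i + 1:j], 16)))
            i = j + 1
        else:
            out.append(c)
            i += 1
    return "".join(out)


def _enc_key(raw: str) -> str:
    if _SAFE_KEY.match(raw) and not raw.startswith("vK") and raw not in _GML_RESERVED:
        return raw
    return "vK" + _esc(raw)


def _dec_key(enc: str) -> str:
    if enc.startswith("vK"):
        return _unesc(enc[2:])
    return enc


def _enc_value(v):
    if isinstance(v, bool):
        return "vB:1" if v else "vB:0"
    if isinstance(v, str) and v.startswith("vB:"):
        return "vB:s:" + v[3:]
    return v


def _dec_value(v):
    if isinstance(v, str) and v.startswith("vB:"):
        rest = v[3:]
        if rest == "1":
            return True
        if rest == "0":
            return False
        if rest.startswith("s:"):
            return "vB:" + rest[2:]
    return v


def _nest(flat: dict) -> dict:
    """Flat dotted-path dict -> nested dict of GML records, keys escaped."""
    tree: dict = {}
    for path, value in flat.items():
        parts = [_enc_key(p) for p in path.split(".")]
        cur = tree
        for p in parts[:-1]:
            nxt = cur.get(p)
            if not isinstance(nxt, dict):
                new: dict = {}
                if p in cur:  # scalar already there: keep it as a leaf
                    new[_STRUCT_LEAF] = cur[p]
                cur[p] = new
                nxt = new
            cur = nxt
        leaf = parts[-1]
        if isinstance(cur.get(leaf), dict):
            cur[leaf][_STRUCT_LEAF] = _enc_value(value)
        else:
            cur[leaf] = _enc_value(value)
    return tree


def _flatten(tree: dict, prefix: str = "") -> dict:
    flat = {}
    for k, v in tree.items():
        if k == _STRUCT_LEAF:
            flat[prefix[:-1]] = _dec_value(v)  # strip trailing dot
            continue
        path = prefix + _dec_key(k)
        if isinstance(v, dict):
            flat.update(_flatten(v, path + "."))
        else:
            flat[path] = _dec_value(v)
    return flat


# ---------------------------------------------------------------------------
# GML


def _write_gml(g: AttributedGraph, path: Path) -> None:
    h = nx.MultiDiGraph()
    for k, v in _nest(g.graph_attrs).items():
        h.graph[k] = v
    order = {n: i for i, n in enumerate(g.nodes)}
    for n in g.nodes:
        attrs = _nest(g.attrs("node", n))
        attrs[_STRUCT_NODE_ID] = n
        h.add_node(order[n], **attrs)
    for (u, v, k) in g.edges:
        attrs = _nest(g.attrs("edge", (u, v, k)))
        attrs[_STRUCT_EDGE_ID] = k
        h.add_edge(order[u], order[v], **attrs)
    nx.write_gml(h, path)


def _read_gml(path: Path) -> AttributedGraph:
    try:
        h = nx.read_gml(path, label=None)
    except nx.NetworkXError as e:
        raise ParseError(f"{path}: malformed GML: {e}") from e
    g = AttributedGraph()
    if not h.is_multigraph():
        h = nx.MultiDiGraph(h) if h.is_directed() else nx.MultiDiGraph(h.to_directed())
    names = {}
    for n, d in h.nodes(data=True):
        d = dict(d)
        raw_label = d.pop("label", None)  # networkx's copy of str(node) for our files
        nid = str(d.pop(_STRUCT_NODE_ID, str(n)))
        names[n] = nid
        flat = _flatten(d)
        if "label" not in flat and raw_label is not None:
            flat["label"] = raw_label  # foreign GML: the label block is authoritative
        g._g.add_node(nid, **flat)
        g._g.nodes[nid].setdefault("label", str(nid))
        g._g.nodes[nid].setdefault("sbgn_class", "unspecified")
    for u, v, k, d in h.edges(keys=True, data=True):
        d = dict(d)
        eid = d.pop(_STRUCT_EDGE_ID, None)
        g._new_edge(names[u], names[v], _flatten(d), key=eid)
    g.graph_attrs = _flatten({k: v for k, v in h.graph.items()
                              if k not in ("directed", "multigraph")})
    return g


# ---------------------------------------------------------------------------
# GraphML


def _write_graphml(g: AttributedGraph, path: Path) -> None:
    h = nx.MultiDiGraph()
    h.graph.update(g.graph_attrs)
    for n in g.nodes:
        h.add_node(n, **g.attrs("node", n))
    for (u, v, k) in g.edges:
        h.add_edge(u, v, key=k, **g.attrs("edge", (u, v, k)))
    nx.write_graphml(h, path)


def _read_graphml(path: Path) -> AttributedGraph:
    try:
        h = nx.read_graphml(path, force_multigraph=True)
    except Exception as e:
        raise ParseError(f"{path}: malformed GraphML: {e}") from e
    g = AttributedGraph()
    for n, d in h.nodes(data=True):
        g._g.add_node(str(n), **dict(d))
        g._g.nodes[str(n)].setdefault("label", str(n))
        g._g.nodes[str(n)].setdefault("sbgn_class", "unspecified")
    for u, v, k, d in h.edges(keys=True, data=True):
        g._new_edge(str(u), str(v), dict(d), key=str(k))
    g.graph_attrs = {k: v for k, v in h.graph.items()
                     if k not in ("node_default", "edge_default")}
    return g


# ---------------------------------------------------------------------------
# SIF


def _write_sif(g: AttributedGraph, path: Path) -> None:
    lines = []
    connected = set()
    for (u, v, k) in g.edges:
        rel = g.get_attr("edge", (u, v, k), "interaction", "pp")
        lines.append(f"{g.label(u)}\t{rel}\t{g.label(v)}")
        connected.update((u, v))
    for n in g.nodes:
        if n not in connected:
            lines.append(g.label(n))
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def _read_sif(path: Path) -> AttributedGraph:
    g = AttributedGraph()
    byname: dict[str, str] = {}

    def node(name: str) -> str:
        if name not in byname:
            byname[name] = g.add_node(label=name)
        return byname[name]

    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip()
        if not line:
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) == 1:
            node(fields[0])
        elif len(fields) >= 3:
            src, rel = fields[0], fields[1]
            for tgt in fields[2:]:
                g.add_edge(node(src), node(tgt), interaction=rel)
        else:
            raise ParseError(f"{path}:{ln}: SIF line needs 1 or >=3 fields, got {len(fields)}")
    return g


# ---------------------------------------------------------------------------
# SBML (read-only, topology + stoichiometry)


def _read_sbml(path: Path) -> AttributedGraph:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ParseError(f"{path}:{err.getLine()}: {err.getMessage().strip()}")
    model = doc.getModel()
    if model is None:
        raise ParseError(f"{path}: SBML file contains no model")
    g = AttributedGraph()
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        nid = g.add_node(node_id=sp.getId(),
                         label=sp.getName() or sp.getId(),
                         sbgn_class="simple_chemical")
        if sp.getBoundaryCondition():
            g.set_attr("node", nid, "boundary", True)
        if sp.isSetCompartment():
            g.set_attr("node", nid, "compartment", sp.getCompartment())
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        rid = g.add_node(node_id=rx.getId(),
                         label=rx.getName() or rx.getId(),
                         sbgn_class="process")
        g.set_attr("node", rid, "reversible", bool(rx.getReversible()))
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            g.add_edge(ref.getSpecies(), rid,
                       weight=ref.getStoichiometry() if ref.isSetStoichiometry() else 1.0)
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            g.add_edge(rid, ref.getSpecies(),
                       weight=ref.getStoichiometry() if ref.isSetStoichiometry() else 1.0)
    return g


# ---------------------------------------------------------------------------
# public interface


def read_network(path, format: str | None = None) -> AttributedGraph:
    """Load a network file; ``format`` defaults to the file extension."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "xml":
        fmt = "sbml"
    if fmt not in FORMATS:
        raise UnsupportedFormatError(f"unsupported network format {fmt!r} (known: {FORMATS})")
    return {"gml": _read_gml, "graphml": _read_graphml,
            "sif": _read_sif, "sbml": _read_sbml}[fmt](path)


def write_network(g: AttributedGraph, path, format: str | None = None) -> Path:
    """Write ``g``; GML/GraphML keep all attributes, SIF only topology."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    writers = {"gml": _write_gml, "graphml": _write_graphml, "sif": _write_sif}
    if fmt not in writers:
        raise UnsupportedFormatError(f"unsupported output format {fmt!r} (known: {tuple(writers)})")
    writers[fmt](g, path)
    return path
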