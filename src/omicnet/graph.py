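"""Attributed directed multigraph: the universal substrate of the package.

Biological entities (metabolites, enzymes, processes, morphological
parameters) are nodes; relations (conversion, catalysis, correlation) are
edges.  Every element carries a flat dictionary of scalar attributes keyed
by dotted hierarchical paths such as ``graphics.fill`` or
``mapping.Glc.Col-0.1.2``.  Layout follows the screen convention: origin
top-left, y grows downward, the (x, y) anchor is the node center.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

SBGN_CLASSES = ("simple_chemical", "macromolecule", "process", "compartment", "unspecified")

#: separator used to store alternative-identifier lists in a single scalar
ALT_ID_SEP = "|"

Scalar = str | int | float | bool


class GraphStructureError(ValueError):
    """Raised when an operation's structural precondition is violated."""


class MergeConflictError(GraphStructureError):
    """Raised when nodes with conflicting SBGN classes would be fused."""


def escape_path_component(part: str) -> str:
    """Escape ``%`` and ``.`` so arbitrary names can live in dotted paths."""
    return part.replace("%", "%25").replace(".", "%2E")


def unescape_path_component(part: str) -> str:
    return part.replace("%2E", ".").replace("%25", "%")


def attr_path(*parts: str) -> str:
    """Join raw name components into a dotted attribute path."""
    return ".".join(escape_path_component(p) for p in parts)


def split_attr_path(path: str) -> list[str]:
    return [unescape_path_component(p) for p in path.split(".")]


class AttributedGraph:
    """Directed multigraph with string node ids and scalar attributes.

    Thin wrapper over :class:`networkx.MultiDiGraph`; all attribute values
    are scalars (str/int/float/bool) so that every attribute survives a
    GML or GraphML round trip verbatim.
    """

    def __init__(self, directed: bool = True):
        self._g = nx.MultiDiGraph()
        self.directed = directed
        self.graph_attrs: dict[str, Scalar] = {}
        self._next_id = 0
        self._next_eid = 0

    # -- basic structure -------------------------------------------------

    @property
    def nx(self) -> nx.MultiDiGraph:
        return self._g

    def fresh_id(self, prefix: str = "n") -> str:
        while True:
            nid = f"{prefix}{self._next_id}"
            self._next_id += 1
            if nid not in self._g:
                return nid

    def add_node(
        self,
        node_id: str | None = None,
        label: str | None = None,
        sbgn_class: str = "unspecified",
        **attrs: Scalar,
    ) -> str:
        if sbgn_class not in SBGN_CLASSES:
            raise ValueError(f"unknown SBGN class {sbgn_class!r}")
        nid = node_id if node_id is not None else self.fresh_id()
        if nid in self._g:
            raise GraphStructureError(f"duplicate node id {nid!r}")
        self._g.add_node(nid, label=label if label is not None else nid, sbgn_class=sbgn_class)
        for k, v in attrs.items():
            self.set_attr("node", nid, k, v)
        return nid

    def _new_edge(self, source: str, target: str, attrs: Mapping[str, Scalar] | None = None,
                  key: str | None = None) -> tuple[str, str, str]:
        if key is None:
            while True:
                key = f"e{self._next_eid}"
                self._next_eid += 1
                if not self._g.has_edge(source, target, key):
                    break
        self._g.add_edge(source, target, key=key)
        if attrs:
            self._g.edges[source, target, key].update(attrs)
        return (source, target, key)

    def add_edge(self, source: str, target: str, **attrs: Scalar) -> tuple[str, str, str]:
        for n in (source, target):
            if n not in self._g:
                raise GraphStructureError(f"edge endpoint {n!r} is not a node")
        edge = self._new_edge(source, target)
        for k, v in attrs.items():
            self.set_attr("edge", edge, k, v)
        return edge

    def remove_node(self, node_id: str) -> None:
        self._g.remove_node(node_id)  # incident edges go with it

    def remove_edge(self, edge: tuple[str, str, str]) -> None:
        self._g.remove_edge(*edge)

    @property
    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    @property
    def edges(self) -> list[tuple[str, str, str]]:
        return list(self._g.edges(keys=True))

    def has_node(self, node_id: str) -> bool:
        return node_id in self._g

    def degree(self, node_id: str) -> int:
        return self._g.degree(node_id)

    def incident_edges(self, node_id: str) -> list[tuple[str, str, str]]:
        inc = list(self._g.in_edges(node_id, keys=True))
        out = [e for e in self._g.out_edges(node_id, keys=True)
               if e[0] != e[1]]  # self loops already in the incoming list
        return inc + out

    # -- attributes ------------------------------------------------------

    def _attr_dict(self, scope: str, element) -> dict:
        if scope == "graph":
            return self.graph_attrs
        if scope == "node":
            return self._g.nodes[element]
        if scope == "edge":
            u, v, k = element
            return self._g.edges[u, v, k]
        raise ValueError(f"unknown scope {scope!r}")

    def set_attr(self, scope: str, element, path: str, value: Scalar) -> None:
        if not isinstance(value, (str, int, float, bool)):
            raise TypeError(f"attribute {path!r}: only scalar values allowed, got {type(value).__name__}")
        self._attr_dict(scope, element)[path] = value

    def get_attr(self, scope: str, element, path: str, default=None):
        return self._attr_dict(scope, element).get(path, default)

    def del_attr(self, scope: str, element, path: str) -> None:
        self._attr_dict(scope, element).pop(path, None)

    def attrs(self, scope: str, element) -> dict[str, Scalar]:
        return dict(self._attr_dict(scope, element))

    def attrs_under(self, scope: str, element, prefix: str) -> dict[str, Scalar]:
        """All attributes whose dotted path starts with ``prefix + '.'``."""
        d = self._attr_dict(scope, element)
        pre = prefix + "."
        return {k: v for k, v in d.items() if k.startswith(pre)}

    # -- node record conveniences ---------------------------------------

    def label(self, node_id: str) -> str:
        return self._g.nodes[node_id].get("label", node_id)

    def set_label(self, node_id: str, label: str) -> None:
        self._g.nodes[node_id]["label"] = label

    def sbgn_class(self, node_id: str) -> str:
        return self._g.nodes[node_id].get("sbgn_class", "unspecified")

    def alt_ids(self, node_id: str) -> list[str]:
        raw = self._g.nodes[node_id].get("alt_ids", "")
        return [s for s in raw.split(ALT_ID_SEP) if s]

    def add_alt_id(self, node_id: str, name: str) -> bool:
        """Append a synonym; returns False when already present (dedup)."""
        ids = self.alt_ids(node_id)
        if name in ids or not name:
            return False
        ids.append(name)
        self._g.nodes[node_id]["alt_ids"] = ALT_ID_SEP.join(ids)
        return True

    def names(self, node_id: str) -> list[str]:
        """Label plus alternative identifiers, in order."""
        return [self.label(node_id)] + self.alt_ids(node_id)

    def position(self, node_id: str) -> tuple[float, float]:
        d = self._g.nodes[node_id]
        return float(d.get("graphics.x", 0.0)), float(d.get("graphics.y", 0.0))

    def set_position(self, node_id: str, x: float, y: float) -> None:
        d = self._g.nodes[node_id]
        d["graphics.x"] = float(x)
        d["graphics.y"] = float(y)

    def size(self, node_id: str) -> tuple[float, float]:
        d = self._g.nodes[node_id]
        return float(d.get("graphics.width", 40.0)), float(d.get("graphics.height", 25.0))

    # -- copying / equality ---------------------------------------------

    def copy(self) -> "AttributedGraph":
        g = AttributedGraph(directed=self.directed)
        g._g = self._g.copy()
        g.graph_attrs = dict(self.graph_attrs)
        g._next_id = self._next_id
        g._next_eid = self._next_eid
        return g

    def equals(self, other: "AttributedGraph") -> bool:
        """Exact equality: same node ids, edges (as multisets) and attributes."""
        if set(self.nodes) != set(other.nodes):
            return False
        if sorted(self.edges) != sorted(other.edges):
            return False
        if self.graph_attrs != other.graph_attrs:
            return False
        for n in self.nodes:
            if self.attrs("node", n) != other.attrs("node", n):
                return False
        for e in self.edges:
            if self.attrs("edge", e) != other.attrs("edge", e):
                return False
        return True

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __repr__(self) -> str:  # pragma: no cover
        return f"<AttributedGraph |V|={len(self)} |E|={self.n_edges()}>"


# ---------------------------------------------------------------------------
# structural editing


def merge_networks(
    graphs: Sequence[AttributedGraph],
    key: str = "label",
    classes: Iterable[str] | None = None,
) -> AttributedGraph:
    """Disjoint union of ``graphs``, then fuse nodes sharing a key value.

    Nodes whose ``key`` attribute values are identical (and whose SBGN class
    is in ``classes``, when given) are collapsed into a single node that
    inherits the union of alternative identifiers and all incident edges.
    Mirrors the pathway-merging step where identical metabolite nodes from
    separately drawn pathways are fused into one network.
    """
    classes = set(classes) if classes is not None else None
    merged = AttributedGraph()
    rename: dict[tuple[int, str], str] = {}

    # disjoint copy with fresh ids
    for gi, g in enumerate(graphs):
        for n in g.nodes:
            nid = merged.fresh_id()
            rename[(gi, n)] = nid
            merged._g.add_node(nid, **g.attrs("node", n))
        for (u, v, k) in g.edges:
            nu, nv = rename[(gi, u)], rename[(gi, v)]
            merged._new_edge(nu, nv, g.attrs("edge", (u, v, k)))
        for p, val in g.graph_attrs.items():
            merged.graph_attrs.setdefault(p, val)

    # group by key value
    groups: dict[Scalar, list[str]] = {}
    for n in merged.nodes:
        if classes is not None and merged.sbgn_class(n) not in classes:
            continue
        val = merged.get_attr("node", n, key)
        if val is None:
            continue
        groups.setdefault(val, []).append(n)

    for val, members in groups.items():
        if len(members) < 2:
            continue
        kinds = {merged.sbgn_class(n) for n in members}
        if len(kinds) > 1:
            raise MergeConflictError(
                f"cannot fuse nodes with key {val!r}: conflicting SBGN classes "
                f"{sorted(kinds)} on nodes {sorted(members)}"
            )
        keep, rest = members[0], members[1:]
        for n in rest:
            for syn in merged.names(n):
                if syn != merged.label(keep):
                    merged.add_alt_id(keep, syn)
            for (u, v, k) in list(merged._g.in_edges(n, keys=True)):
                nu = keep if u == n else u
                merged._new_edge(nu, keep, merged.attrs("edge", (u, v, k)))
            for (u, v, k) in list(merged._g.out_edges(n, keys=True)):
                if u == n and v == n:
                    continue  # self loop already moved with in_edges
                merged._new_edge(keep, v, merged.attrs("edge", (u, v, k)))
            merged._g.remove_node(n)
    return merged


def split_node(g: AttributedGraph, node: str) -> AttributedGraph:
    """Replace a high-degree node by one clone per incident edge.

    Used for frequently occurring currency metabolites such as ATP or CO2:
    each clone keeps the label and synonyms, carries ``clone_of`` and
    ``clone_count`` attributes, and takes over exactly one incident edge.
    Degree < 2 is a no-op (nothing to untangle).
    """
    out = g.copy()
    edges = out.incident_edges(node)
    if len(edges) < 2:
        return out
    base_attrs = out.attrs("node", node)
    d = len(edges)
    for i, (u, v, k) in enumerate(edges):
        clone = out.fresh_id()
        out._g.add_node(clone, **base_attrs)
        out.set_attr("node", clone, "clone_of", node)
        out.set_attr("node", clone, "clone_count", d)
        eattrs = out.attrs("edge", (u, v, k))
        nu = clone if u == node else u
        nv = clone if v == node else v
        out._new_edge(nu, nv, eattrs)
    out._g.remove_node(node)
    return out


_NUMERIC_EXPRS = {"mean", "median", "min", "max"}


def compute_attribute(
    g: AttributedGraph,
    scope: str,
    expression: str,
    source: str | None,
    target: str,
) -> tuple[AttributedGraph, int]:
    """Derive a new attribute per element from existing numeric attributes.

    ``source`` is a dotted-path prefix; all numeric attributes below it feed
    the aggregate.  ``expression`` is one of mean/median/min/max/degree.
    Returns the updated graph and the number of elements written.
    """
    import statistics

    if expression not in _NUMERIC_EXPRS and expression != "degree":
        raise ValueError(f"unknown expression {expression!r}")
    out = g.copy()
    elements = out.nodes if scope == "node" else out.edges
    written = 0
    for el in elements:
        if expression == "degree":
            if scope != "node":
                raise ValueError("degree applies to nodes only")
            out.set_attr("node", el, target, out.degree(el))
            written += 1
            continue
        pool = out.attrs_under(scope, el, source) if source else {}
        if source in out._attr_dict(scope, el):
            pool[source] = out.get_attr(scope, el, source)
        values = [v for v in pool.values() if isinstance(v, (int, float)) and not isinstance(v, bool)]
        if not values:
            continue  # element skipped: nothing numeric under the source path
        fn = {"mean": statistics.fmean, "median": statistics.median, "min": min, "max": max}[expression]
        out.set_attr(scope, el, target, fn(values))
        written += 1
    return out, written
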