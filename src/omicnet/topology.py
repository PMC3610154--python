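"""Structural network analysis: paths, cycles, motifs, centralities.

All operations read an :class:`AttributedGraph` and either return plain
results or write per-node attributes under ``centrality.<measure>`` so
that downstream rendering and export can pick them up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from .graph import AttributedGraph, GraphStructureError

CENTRALITY_MEASURES = ("degree_in", "degree_out", "degree", "closeness",
                       "eccentricity", "betweenness", "eigenvector", "katz")


# ---------------------------------------------------------------------------
# shortest paths


def shortest_paths(
    g: AttributedGraph,
    source: str,
    target: str | None = None,
    weight: str | None = None,
):
    """Shortest path(s) from ``source``.

    Unweighted graphs use BFS, nonnegative edge weights Dijkstra.  With a
    ``target``: returns ``(path, length)`` where an unreachable target is
    ``(None, inf)``.  Without: returns ``{node: (path, length)}`` for every
    reachable node.
    """
    for n in (source, target) if target else (source,):
        if n is not None and not g.has_node(n):
            raise KeyError(f"node {n!r} not in graph")
    h = g.nx
    if weight is not None:
        for e in g.edges:
            w = g.get_attr("edge", e, weight, 1)
            if w < 0:
                raise ValueError(f"negative weight on edge {e}")
    try:
        lengths, paths = nx.single_source_dijkstra(h, source, weight=weight or None)
    except nx.NetworkXNoPath:  # pragma: no cover - dijkstra returns partial maps
        lengths, paths = {}, {}
    if target is not None:
        if target not in lengths:
            return None, math.inf
        return paths[target], lengths[target]
    return {n: (paths[n], lengths[n]) for n in lengths}


def all_pairs_distances(g: AttributedGraph, weight: str | None = None) -> dict:
    """Distance matrix as nested dict; missing entries mean unreachable."""
    return {s: {t: d for t, d in row.items()}
            for s, row in nx.all_pairs_dijkstra_path_length(g.nx, weight=weight or None)}


# ---------------------------------------------------------------------------
# cycles


def find_cycles(g: AttributedGraph, directed: bool | None = None,
                cap: int = 10000) -> tuple[list[list[str]], bool]:
    """Cycle enumeration.

    Directed: all elementary circuits (Johnson's algorithm), capped at
    ``cap`` with a truncation flag.  Undirected view: a cycle basis.
    Returns ``(cycles, truncated)``.
    """
    if directed is None:
        directed = g.directed
    if directed:
        cycles = []
        truncated = False
        for c in nx.simple_cycles(g.nx):
            if len(cycles) >= cap:
                truncated = True
                break
            cycles.append(list(c))
        return cycles, truncated
    basis = nx.cycle_basis(nx.Graph(g.nx.to_undirected()))
    return [list(c) for c in basis], False


# ---------------------------------------------------------------------------
# motifs


@dataclass
class MotifQuery:
    """A small connected pattern graph, optionally class-constrained.

    Pattern nodes with an SBGN class other than ``unspecified`` only match
    host nodes of the same class.
    """

    pattern: AttributedGraph
    directed: bool = True
    induced: bool = False

    def __post_init__(self):
        if len(self.pattern) > 8:
            raise ValueError("motif patterns are limited to 8 nodes")
        und = self.pattern.nx.to_undirected()
        if len(self.pattern) and not nx.is_connected(nx.Graph(und)):
            raise ValueError("motif pattern must be connected")


def feed_forward_loop() -> MotifQuery:
    """The classic 3-node feed-forward loop A->B, A->C, B->C."""
    p = AttributedGraph()
    a, b, c = (p.add_node(label=x) for x in "ABC")
    p.add_edge(a, b)
    p.add_edge(a, c)
    p.add_edge(b, c)
    return MotifQuery(p)


def find_motifs(g: AttributedGraph, q: MotifQuery) -> list[tuple[str, ...]]:
    """All injective matches of the pattern, deduplicated by automorphism.

    Default matching is non-induced (every pattern arc must exist in the
    host; extra host arcs are allowed); ``induced`` additionally forbids
    host arcs absent from the pattern.  Matches are ordered node tuples
    following the pattern's node order.
    """
    pat = nx.DiGraph(q.pattern.nx)
    host = nx.DiGraph(g.nx) if q.directed else nx.Graph(g.nx.to_undirected())
    if not q.directed:
        pat = nx.Graph(pat.to_undirected())
    if len(pat) > len(host.nodes):
        return []

    classes = {n: q.pattern.sbgn_class(n) for n in q.pattern.nodes}
    pat_nodes = list(pat.nodes)
    matcher_cls = (nx.isomorphism.DiGraphMatcher if q.directed
                   else nx.isomorphism.GraphMatcher)
    gm = matcher_cls(host, pat)
    it = (gm.subgraph_isomorphisms_iter() if q.induced
          else gm.subgraph_monomorphisms_iter())
    autos = [dict(m) for m in matcher_cls(pat, pat).isomorphisms_iter()]

    seen: set[tuple] = set()
    out: list[tuple[str, ...]] = []
    for m in it:  # m: host node -> pattern node
        inv = {pn: hn for hn, pn in m.items()}
        # class constraints
        ok = all(classes[pn] == "unspecified" or g.sbgn_class(inv[pn]) == classes[pn]
                 for pn in pat_nodes)
        if not ok:
            continue
        tup = tuple(inv[pn] for pn in pat_nodes)
        canon = min(tuple(inv[a[pn]] for pn in pat_nodes) for a in autos)
        if canon in seen:
            continue
        seen.add(canon)
        out.append(tup)
    return sorted(out)


# ---------------------------------------------------------------------------
# centralities


def centralities(
    g: AttributedGraph,
    which=CENTRALITY_MEASURES,
    store: bool = True,
) -> tuple[AttributedGraph, dict[str, dict[str, float]]]:
    """Compute named centralities; store as ``centrality.<measure>``.

    Conventions: degrees are raw counts; closeness is the harmonic variant
    (sum of reciprocal distances), well defined on disconnected graphs;
    eccentricity is computed within each (weakly) connected component;
    betweenness uses Brandes' algorithm with unnormalized pair counting;
    eigenvector centrality is computed by power iteration on the
    undirected view (tolerance 1e-10, at most 10^4 iterations).
    """
    h = g.nx
    simple_d = nx.DiGraph(h)
    simple_u = nx.Graph(h.to_undirected())
    values: dict[str, dict[str, float]] = {}
    for m in which:
        if m == "degree_in":
            values[m] = {n: float(d) for n, d in h.in_degree()}
        elif m == "degree_out":
            values[m] = {n: float(d) for n, d in h.out_degree()}
        elif m == "degree":
            values[m] = {n: float(d) for n, d in h.degree()}
        elif m == "closeness":
            values[m] = {n: float(v) for n, v in
                         nx.harmonic_centrality(simple_u).items()}
        elif m == "eccentricity":
            vals = {}
            for comp in nx.connected_components(simple_u):
                sub = simple_u.subgraph(comp)
                vals.update(nx.eccentricity(sub))
            values[m] = {n: float(v) for n, v in vals.items()}
        elif m == "betweenness":
            values[m] = {n: float(v) for n, v in
                         nx.betweenness_centrality(simple_u, normalized=False).items()}
        elif m == "eigenvector":
            try:
                values[m] = {n: float(v) for n, v in
                             nx.eigenvector_centrality(simple_u, max_iter=10000,
                                                       tol=1e-10).items()}
            except nx.PowerIterationFailedConvergence as e:
                raise RuntimeError(f"eigenvector centrality did not converge: {e}") from e
        elif m == "katz":
            values[m] = {n: float(v) for n, v in
                         nx.katz_centrality(simple_d, alpha=0.05, max_iter=10000,
                                            tol=1e-10).items()}
        else:
            raise ValueError(f"unknown centrality {m!r}")
    out = g
    if store:
        out = g.copy()
        for m, vals in values.items():
            for n, v in vals.items():
                out.set_attr("node", n, f"centrality.{m}", v)
    return out, values
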