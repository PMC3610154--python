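"""Discrete Petri nets derived from metabolic networks.

Metabolites become places, processes become transitions, stoichiometric
edge weights become arc weights; a reversible process expands into two
opposing transitions.  The incidence matrix C = post - pre drives the
token game (M' = M + C e_t), P/T-invariant computation (Farkas
elimination, exact integer arithmetic) and reachability-graph
construction (BFS over firings).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .graph import AttributedGraph, GraphStructureError


class FiringError(ValueError):
    """A disabled transition was asked to fire."""


@dataclass
class PetriNet:
    places: list[str]
    transitions: list[str]
    pre: np.ndarray      # (places x transitions) arc weights place -> transition
    post: np.ndarray     # (places x transitions) arc weights transition -> place
    marking: np.ndarray  # nonnegative integer token counts per place

    def __post_init__(self):
        self.pre = np.asarray(self.pre, dtype=np.int64)
        self.post = np.asarray(self.post, dtype=np.int64)
        self.marking = np.asarray(self.marking, dtype=np.int64)
        p, t = len(self.places), len(self.transitions)
        if self.pre.shape != (p, t) or self.post.shape != (p, t):
            raise ValueError("pre/post matrices inconsistent with place/transition lists")
        if self.marking.shape != (p,):
            raise ValueError("marking length != number of places")
        if (self.pre < 0).any() or (self.post < 0).any() or (self.marking < 0).any():
            raise ValueError("arc weights and markings must be nonnegative")

    @property
    def incidence(self) -> np.ndarray:
        """C = post - pre; column t is the token change of firing t."""
        return self.post - self.pre

    def enabled(self, transition: int | str) -> bool:
        t = self._tindex(transition)
        return bool((self.marking >= self.pre[:, t]).all())

    def enabled_transitions(self) -> list[int]:
        return [t for t in range(len(self.transitions)) if self.enabled(t)]

    def _tindex(self, transition: int | str) -> int:
        if isinstance(transition, str):
            return self.transitions.index(transition)
        return transition

    def with_marking(self, marking) -> "PetriNet":
        return PetriNet(self.places, self.transitions, self.pre, self.post,
                        np.asarray(marking, dtype=np.int64))


@dataclass
class Invariant:
    vector: np.ndarray
    side: str  # "place" or "transition"

    @property
    def support(self) -> tuple[int, ...]:
        return tuple(int(i) for i in np.nonzero(self.vector)[0])


@dataclass
class ReachabilityGraph:
    states: list[tuple[int, ...]]
    arcs: list[tuple[tuple[int, ...], int, tuple[int, ...]]]
    initial: tuple[int, ...]
    truncated: bool = False


# ---------------------------------------------------------------------------
# construction from a metabolic network


def to_petri_net(g: AttributedGraph) -> PetriNet:
    """Translate a bipartite metabolic graph into a place/transition net.

    ``simple_chemical`` nodes are places, ``process`` nodes transitions;
    edge weights (default 1) must be integral.  Reversible processes (node
    attribute ``reversible``) expand into two opposing transitions.  The
    initial marking comes from node attribute ``marking`` (default 0).
    """
    places, procs = [], []
    for n in g.nodes:
        c = g.sbgn_class(n)
        if c == "simple_chemical":
            places.append(n)
        elif c == "process":
            procs.append(n)
        else:
            raise GraphStructureError(
                f"node {n!r} has class {c!r}; Petri translation needs "
                "simple_chemical/process bipartition")
    pidx = {p: i for i, p in enumerate(places)}
    procset = set(procs)
    for (u, v, _k) in g.edges:
        if (u in pidx) == (v in pidx) or (u in procset) == (v in procset):
            raise GraphStructureError(
                f"edge {u!r}->{v!r} connects two same-class nodes")

    transitions: list[str] = []
    cols_pre: list[np.ndarray] = []
    cols_post: list[np.ndarray] = []
    for t in procs:
        pre = np.zeros(len(places), dtype=np.int64)
        post = np.zeros(len(places), dtype=np.int64)
        for (u, v, k) in g.incident_edges(t):
            other = u if v == t else v
            if other not in pidx:
                raise GraphStructureError(
                    f"edge {u!r}->{v!r} connects two same-class nodes")
            w = g.get_attr("edge", (u, v, k), "weight", 1)
            wi = int(round(float(w)))
            if not math.isclose(float(w), wi) or wi < 1:
                raise GraphStructureError(
                    f"edge {u!r}->{v!r}: weight {w} is not a positive integer")
            if v == t:
                pre[pidx[other]] += wi
            else:
                post[pidx[other]] += wi
        transitions.append(t)
        cols_pre.append(pre)
        cols_post.append(post)
        if g.get_attr("node", t, "reversible", False):
            transitions.append(f"{t}__rev")
            cols_pre.append(post.copy())
            cols_post.append(pre.copy())
    pre = np.column_stack(cols_pre) if cols_pre else np.zeros((len(places), 0), dtype=np.int64)
    post = np.column_stack(cols_post) if cols_post else np.zeros((len(places), 0), dtype=np.int64)
    marking = np.array([int(g.get_attr("node", p, "marking", 0)) for p in places],
                       dtype=np.int64)
    return PetriNet(places, transitions, pre, post, marking)


# ---------------------------------------------------------------------------
# token game


def fire(net: PetriNet, transition: int | str) -> PetriNet:
    """Fire one transition: M' = M + C e_t; disabled firing is an error."""
    t = net._tindex(transition)
    if not net.enabled(t):
        raise FiringError(f"transition {net.transitions[t]!r} is not enabled")
    return net.with_marking(net.marking + net.incidence[:, t])


def simulate(net: PetriNet, steps: int, policy: str = "random_seeded",
             seed: int = 0) -> list[tuple[int, ...]]:
    """Run the token game; returns the marking trace (initial included).

    ``random_seeded`` fires one uniformly chosen enabled transition per
    step; ``maximal`` fires every enabled transition once, sequentially in
    index order, skipping those disabled by earlier firings in the same
    step.  Stops early on a dead marking.
    """
    rng = np.random.default_rng(seed)
    cur = net
    trace = [tuple(int(v) for v in cur.marking)]
    for _ in range(steps):
        enabled = cur.enabled_transitions()
        if not enabled:
            break
        if policy == "random_seeded":
            cur = fire(cur, int(rng.choice(enabled)))
        elif policy == "maximal":
            for t in enabled:
                if cur.enabled(t):
                    cur = fire(cur, t)
        else:
            raise ValueError(f"unknown policy {policy!r}")
        trace.append(tuple(int(v) for v in cur.marking))
    return trace


# ---------------------------------------------------------------------------
# invariants (Farkas elimination, exact integers)


def _gcd_normalize(v: np.ndarray) -> np.ndarray:
    g = 0
    for x in v:
        g = math.gcd(g, int(x))
    return v // g if g > 1 else v


def _farkas(matrix: np.ndarray) -> list[np.ndarray]:
    """Minimal-support nonnegative integer left-null-space generators.

    Farkas / Fourier-Motzkin elimination on [A | I]: columns of A are
    eliminated one by one, combining rows with opposite signs using exact
    integer arithmetic; afterwards rows whose support strictly contains
    another row's are discarded and entries are gcd-normalized.
    """
    a = [[int(x) for x in row] for row in matrix]
    n_rows = len(a)
    n_cols = len(a[0]) if n_rows else 0
    # tableau rows: (a_row, identity_row)
    tab = [(list(a[i]), [1 if j == i else 0 for j in range(n_rows)])
           for i in range(n_rows)]
    for col in range(n_cols):
        keep = [row for row in tab if row[0][col] == 0]
        pos = [row for row in tab if row[0][col] > 0]
        neg = [row for row in tab if row[0][col] < 0]
        for rp in pos:
            for rn in neg:
                cp, cn = rp[0][col], -rn[0][col]
                g = math.gcd(cp, cn)
                mp, mn = cn // g, cp // g
                new_a = [mp * x + mn * y for x, y in zip(rp[0], rn[0])]
                new_i = [mp * x + mn * y for x, y in zip(rp[1], rn[1])]
                keep.append((new_a, new_i))
        tab = keep
    vectors = []
    for _arow, irow in tab:
        v = np.array(irow, dtype=object)
        if (v == 0).all():
            continue
        vectors.append(_gcd_normalize(v))
    # minimal support + dedup
    out: list[np.ndarray] = []
    supports = [frozenset(int(i) for i in np.nonzero(v)[0]) for v in vectors]
    for i, v in enumerate(vectors):
        s = supports[i]
        minimal = True
        for j, t in enumerate(supports):
            if i == j:
                continue
            if t < s or (t == s and j < i and (vectors[j] == v).all()):
                minimal = False
                break
        if minimal and not any((w == v).all() for w in out):
            out.append(v)
    return [v.astype(np.int64) for v in out]


def invariants(net: PetriNet, side: str = "place") -> list[Invariant]:
    """Minimal-support P- or T-invariants of the incidence matrix.

    P-invariants x satisfy x^T C = 0 (weighted token conservation);
    T-invariants x satisfy C x = 0 (firing-count vectors returning to the
    start marking).  Exact integer arithmetic throughout.
    """
    c = net.incidence
    if side == "place":
        vecs = _farkas(c)
    elif side == "transition":
        vecs = _farkas(c.T)
    else:
        raise ValueError("side must be 'place' or 'transition'")
    return [Invariant(v, side) for v in vecs]


# ---------------------------------------------------------------------------
# reachability


def reachability(net: PetriNet, max_states: int = 100_000) -> ReachabilityGraph:
    """BFS over firings from the initial marking, capped at ``max_states``."""
    if max_states < 1:
        raise ValueError("max_states must be >= 1")
    from collections import deque

    init = tuple(int(v) for v in net.marking)
    states = {init}
    order = [init]
    arcs = []
    queue = deque([init])
    truncated = False
    while queue:
        m = queue.popleft()
        cur = net.with_marking(np.array(m, dtype=np.int64))
        for t in cur.enabled_transitions():
            nxt = tuple(int(v) for v in cur.marking + cur.incidence[:, t])
            if nxt not in states:
                if len(states) >= max_states:
                    truncated = True
                    continue
                states.add(nxt)
                order.append(nxt)
                queue.append(nxt)
            arcs.append((m, t, nxt))
    return ReachabilityGraph(order, arcs, init, truncated)


# ---------------------------------------------------------------------------
# PNML interchange (basic place/transition subset)


def write_pnml(net: PetriNet, path) -> None:
    from lxml import etree

    ns = "http://www.pnml.org/version-2009/grammar/pnml"
    root = etree.Element("pnml", nsmap={None: ns})
    netel = etree.SubElement(root, "net", id="net0",
                             type="http://www.pnml.org/version-2009/grammar/ptnet")
    page = etree.SubElement(netel, "page", id="page0")

    def with_name(el, name):
        t = etree.SubElement(etree.SubElement(el, "name"), "text")
        t.text = name

    for i, p in enumerate(net.places):
        el = etree.SubElement(page, "place", id=f"p{i}")
        with_name(el, p)
        if net.marking[i]:
            t = etree.SubElement(etree.SubElement(el, "initialMarking"), "text")
            t.text = str(int(net.marking[i]))
    for j, t_name in enumerate(net.transitions):
        el = etree.SubElement(page, "transition", id=f"t{j}")
        with_name(el, t_name)
    arc_id = 0
    for i in range(len(net.places)):
        for j in range(len(net.transitions)):
            for (w, src, tgt) in ((net.pre[i, j], f"p{i}", f"t{j}"),
                                  (net.post[i, j], f"t{j}", f"p{i}")):
                if w:
                    el = etree.SubElement(page, "arc", id=f"a{arc_id}",
                                          source=src, target=tgt)
                    arc_id += 1
                    if w > 1:
                        txt = etree.SubElement(etree.SubElement(el, "inscription"), "text")
                        txt.text = str(int(w))
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="UTF-8")


def read_pnml(path) -> PetriNet:
    from lxml import etree

    tree = etree.parse(str(path))
    ns = {"p": "http://www.pnml.org/version-2009/grammar/pnml"}

    def text_of(el, tag):
        found = el.find(f"p:{tag}/p:text", ns)
        return found.text if found is not None else None

    places, trans = [], []
    pid, tid = {}, {}
    marking = []
    for el in tree.iter(f"{{{ns['p']}}}place"):
        pid[el.get("id")] = len(places)
        places.append(text_of(el, "name") or el.get("id"))
        m = text_of(el, "initialMarking")
        marking.append(int(m) if m else 0)
    for el in tree.iter(f"{{{ns['p']}}}transition"):
        tid[el.get("id")] = len(trans)
        trans.append(text_of(el, "name") or el.get("id"))
    pre = np.zeros((len(places), len(trans)), dtype=np.int64)
    post = np.zeros((len(places), len(trans)), dtype=np.int64)
    for el in tree.iter(f"{{{ns['p']}}}arc"):
        src, tgt = el.get("source"), el.get("target")
        w = int(text_of(el, "inscription") or 1)
        if src in pid and tgt in tid:
            pre[pid[src], tid[tgt]] += w
        elif src in tid and tgt in pid:
            post[pid[tgt], tid[src]] += w
        else:
            raise ValueError(f"{path}: arc {el.get('id')} does not connect "
                             "a place and a transition")
    return PetriNet(places, trans, pre, post, np.array(marking, dtype=np.int64))
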