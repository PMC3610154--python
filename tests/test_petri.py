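"""Petri-net translation, token game, invariants, reachability."""

import itertools
import math

import numpy as np
import pytest

from omicnet.graph import AttributedGraph, GraphStructureError
from omicnet.petri import (FiringError, PetriNet, fire, invariants, reachability,
                           read_pnml, simulate, to_petri_net, write_pnml)
from omicnet.synth import generate_network


def simple_net(marking=(1, 0)):
    """P1 -t-> P2."""
    return PetriNet(["P1", "P2"], ["t"],
                    pre=np.array([[1], [0]]), post=np.array([[0], [1]]),
                    marking=np.array(marking))


def bounded_invariant_search(C, side, bound=3):
    """Brute force: all gcd-normalized minimal-support nonnegative vectors
    with entries <= bound annihilating C (or C^T)."""
    A = C if side == "place" else C.T
    n = A.shape[0]
    sols = []
    for combo in itertools.product(range(bound + 1), repeat=n):
        v = np.array(combo)
        if not v.any():
            continue
        if (v @ A == 0).all():
            g = np.gcd.reduce(v[v > 0])
            sols.append(tuple(v // g))
    sols = sorted(set(sols))
    minimal = []
    for v in sols:
        sup = {i for i, x in enumerate(v) if x}
        if not any({i for i, x in enumerate(w) if x} < sup for w in sols if w != v):
            minimal.append(v)
    return sorted(set(minimal))


class TestTranslation:
    def test_single_reaction(self):
        g = AttributedGraph()
        a = g.add_node(node_id="A", sbgn_class="simple_chemical")
        b = g.add_node(node_id="B", sbgn_class="simple_chemical")
        r = g.add_node(node_id="r1", sbgn_class="process")
        g.add_edge(a, r)
        g.add_edge(r, b)
        net = to_petri_net(g)
        assert net.places == ["A", "B"] and net.transitions == ["r1"]
        assert net.incidence.tolist() == [[-1], [1]]

    def test_reversible_expands_to_opposite_columns(self):
        g = AttributedGraph()
        a = g.add_node(node_id="A", sbgn_class="simple_chemical")
        b = g.add_node(node_id="B", sbgn_class="simple_chemical")
        r = g.add_node(node_id="r1", sbgn_class="process")
        g.set_attr("node", r, "reversible", True)
        g.add_edge(a, r)
        g.add_edge(r, b)
        net = to_petri_net(g)
        assert len(net.transitions) == 2
        C = net.incidence
        assert (C[:, 0] == -C[:, 1]).all()

    def test_stoichiometry_two_to_one(self):
        g = AttributedGraph()
        a = g.add_node(node_id="A", sbgn_class="simple_chemical")
        b = g.add_node(node_id="B", sbgn_class="simple_chemical")
        r = g.add_node(node_id="r1", sbgn_class="process")
        g.add_edge(a, r, weight=2)
        g.add_edge(r, b, weight=1)
        net = to_petri_net(g)
        assert net.pre[0, 0] == 2
        assert net.incidence[:, 0].tolist() == [-2, 1]

    def test_same_class_edge_rejected(self):
        g = AttributedGraph()
        a = g.add_node(node_id="A", sbgn_class="simple_chemical")
        b = g.add_node(node_id="B", sbgn_class="simple_chemical")
        g.add_edge(a, b)
        with pytest.raises(GraphStructureError, match="same-class"):
            to_petri_net(g)


class TestTokenGame:
    def test_fire_moves_token_then_disables(self):
        net = simple_net()
        net2 = fire(net, "t")
        assert net2.marking.tolist() == [0, 1]
        with pytest.raises(FiringError):
            fire(net2, "t")

    def test_conservative_cycle_token_sum_constant(self):
        cyc = to_petri_net(generate_network("cycle", 4))
        cyc = cyc.with_marking([2, 0, 1, 0])
        trace = simulate(cyc, 30, seed=3)
        assert all(sum(m) == 3 for m in trace)

    def test_seeded_trace_reproducible(self):
        cyc = to_petri_net(generate_network("cycle", 5)).with_marking([1, 0, 0, 1, 0])
        t1 = simulate(cyc, 20, seed=11)
        t2 = simulate(cyc, 20, seed=11)
        assert t1 == t2


class TestInvariants:
    def test_reversible_pair_p_and_t_invariants(self):
        net = PetriNet(["A", "B"], ["f", "b"],
                       pre=np.array([[1, 0], [0, 1]]),
                       post=np.array([[0, 1], [1, 0]]),
                       marking=np.zeros(2))
        p = invariants(net, "place")
        t = invariants(net, "transition")
        assert [list(i.vector) for i in p] == [[1, 1]]
        assert [list(i.vector) for i in t] == [[1, 1]]

    def test_exact_annihilation_and_bruteforce_equality(self):
        rng = np.random.default_rng(17)
        for trial in range(8):
            C = rng.integers(-2, 3, size=(4, 4))
            net = PetriNet([f"p{i}" for i in range(4)], [f"t{j}" for j in range(4)],
                           pre=np.where(C < 0, -C, 0), post=np.where(C > 0, C, 0),
                           marking=np.zeros(4))
            for side, mat in (("place", C), ("transition", C.T)):
                found = invariants(net, side)
                for inv in found:
                    assert (inv.vector @ mat == 0).all()
                    assert np.gcd.reduce(inv.vector[inv.vector > 0]) == 1
                small = [tuple(i.vector) for i in found
                         if (i.vector <= 3).all()]
                assert sorted(small) == bounded_invariant_search(C, side)

    def test_net_without_invariants(self):
        # pure source: t produces into P with nothing consumed
        net = PetriNet(["P"], ["t"], pre=np.array([[0]]), post=np.array([[1]]),
                       marking=np.array([0]))
        assert invariants(net, "place") == []


class TestReachability:
    def test_two_token_chain_states(self):
        net = simple_net(marking=(2, 0))
        rg = reachability(net)
        assert sorted(rg.states) == [(0, 2), (1, 1), (2, 0)]
        assert len(rg.arcs) == 2 and not rg.truncated

    def test_dead_initial_marking(self):
        net = simple_net(marking=(0, 0))
        rg = reachability(net)
        assert rg.states == [(0, 0)] and rg.arcs == []

    def test_equals_bruteforce_bfs_on_small_nets(self):
        rng = np.random.default_rng(23)
        for trial in range(5):
            p, t = 4, 3
            pre = rng.integers(0, 2, size=(p, t))
            post = rng.integers(0, 2, size=(p, t))
            net = PetriNet([f"p{i}" for i in range(p)], [f"t{j}" for j in range(t)],
                           pre=pre, post=post, marking=rng.integers(0, 2, size=p))
            rg = reachability(net, max_states=500)
            if rg.truncated:
                continue
            # independent BFS with explicit firing rule
            C = post - pre
            seen = {tuple(int(x) for x in net.marking)}
            frontier = [np.array(net.marking)]
            arcs = 0
            while frontier:
                nxt = []
                for m in frontier:
                    for j in range(t):
                        if (m >= pre[:, j]).all():
                            arcs += 1
                            m2 = tuple(int(x) for x in (m + C[:, j]))
                            if m2 not in seen:
                                seen.add(m2)
                                nxt.append(np.array(m2))
                frontier = nxt
            assert set(rg.states) == seen
            assert len(rg.arcs) == arcs

    def test_p_invariants_conserved_over_reachable_set(self):
        cyc = to_petri_net(generate_network("cycle", 4)).with_marking([2, 1, 0, 0])
        rg = reachability(cyc)
        for inv in invariants(cyc, "place"):
            ref = inv.vector @ cyc.marking
            for m in rg.states:
                assert inv.vector @ np.array(m) == ref

    def test_simulation_stays_inside_reachability_graph(self):
        cyc = to_petri_net(generate_network("cycle", 5)).with_marking([1, 1, 0, 0, 0])
        rg = reachability(cyc)
        trace = simulate(cyc, 25, seed=2)
        assert set(trace) <= set(rg.states)

    def test_unbounded_net_truncates(self):
        net = PetriNet(["P"], ["t"], pre=np.array([[0]]), post=np.array([[1]]),
                       marking=np.array([0]))
        rg = reachability(net, max_states=10)
        assert rg.truncated and len(rg.states) == 10


class TestPnml:
    def test_roundtrip(self, tmp_path):
        g = generate_network("cycle", 3)
        net = to_petri_net(g).with_marking([2, 0, 1])
        p = tmp_path / "net.pnml"
        write_pnml(net, p)
        back = read_pnml(p)
        assert back.places == net.places
        assert back.transitions == net.transitions
        assert (back.pre == net.pre).all() and (back.post == net.post).all()
        assert (back.marking == net.marking).all()
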