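"""Constraint-based analysis of stoichiometric models.

Flux balance analysis (FBA) maximizes a linear flux objective c^T v under
steady-state mass balance S v = 0 and flux bounds lb <= v <= ub; flux
variability analysis (FVA) reports each reaction's attainable range while
the objective is held at (a fraction of) its optimum; knockout fixes a
reaction to zero and re-solves; robustness scans the objective as one
reaction is clamped across its feasible range.  LPs are solved with the
HiGHS solver behind :func:`scipy.optimize.linprog`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .graph import AttributedGraph, GraphStructureError

FEAS_TOL = 1e-9


class ModelError(ValueError):
    pass


@dataclass
class StoichModel:
    S: np.ndarray                 # metabolites x reactions
    lb: np.ndarray
    ub: np.ndarray
    c: np.ndarray                 # objective coefficients (maximized)
    reactions: list[str]
    metabolites: list[str]

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        m, r = self.S.shape
        if not (len(self.lb) == len(self.ub) == len(self.c) == len(self.reactions) == r):
            raise ModelError("dimension mismatch between S and vectors")
        if len(self.metabolites) != m:
            raise ModelError("metabolite list inconsistent with S")
        if (self.lb > self.ub).any():
            bad = [self.reactions[i] for i in np.nonzero(self.lb > self.ub)[0]]
            raise ModelError(f"lb > ub for reactions {bad}")

    def reaction_index(self, name: str) -> int:
        try:
            return self.reactions.index(name)
        except ValueError:
            raise KeyError(f"unknown reaction {name!r}") from None

    def copy(self) -> "StoichModel":
        return StoichModel(self.S.copy(), self.lb.copy(), self.ub.copy(),
                           self.c.copy(), list(self.reactions), list(self.metabolites))


@dataclass
class FluxSolution:
    v: np.ndarray | None
    objective: float | None
    status: str  # optimal | infeasible | unbounded

    def flux(self, model: StoichModel, reaction: str) -> float:
        return float(self.v[model.reaction_index(reaction)])


def from_graph(
    g: AttributedGraph,
    objective: str,
    default_bound: float = 1000.0,
) -> StoichModel:
    """Build a stoichiometric model from a bipartite metabolic graph.

    Process nodes become reactions; edge weights become stoichiometric
    coefficients (consumed negative, produced positive).  Metabolites
    flagged with attribute ``boundary`` are dropped from the balance rows,
    so processes touching only boundary metabolites act as exchange
    reactions.  Reversible processes get lb = -default_bound, irreversible
    lb = 0; node attributes ``lb``/``ub`` override.
    """
    mets, procs = [], []
    for n in g.nodes:
        cls = g.sbgn_class(n)
        if cls == "simple_chemical":
            if not g.get_attr("node", n, "boundary", False):
                mets.append(n)
        elif cls == "process":
            procs.append(n)
        else:
            raise GraphStructureError(f"node {n!r}: class {cls!r} not allowed in "
                                      "a metabolic graph")
    if objective not in procs:
        raise ModelError(f"objective reaction {objective!r} not in the network")
    midx = {m: i for i, m in enumerate(mets)}
    S = np.zeros((len(mets), len(procs)))
    lb = np.zeros(len(procs))
    ub = np.full(len(procs), default_bound)
    for j, t in enumerate(procs):
        for (u, v, k) in g.incident_edges(t):
            other = u if v == t else v
            if other not in midx:
                continue  # boundary metabolite: unbalanced by design
            w = float(g.get_attr("edge", (u, v, k), "weight", 1.0))
            if v == t:
                S[midx[other], j] -= w
            else:
                S[midx[other], j] += w
        if g.get_attr("node", t, "reversible", False):
            lb[j] = -default_bound
        lba = g.get_attr("node", t, "lb")
        uba = g.get_attr("node", t, "ub")
        if lba is not None:
            lb[j] = float(lba)
        if uba is not None:
            ub[j] = float(uba)
    c = np.zeros(len(procs))
    c[procs.index(objective)] = 1.0
    return StoichModel(S, lb, ub, c, procs, mets)


def _solve(model: StoichModel, c: np.ndarray, extra_A=None, extra_b=None) -> FluxSolution:
    res = linprog(
        -c,
        A_eq=model.S, b_eq=np.zeros(model.S.shape[0]),
        A_ub=extra_A, b_ub=extra_b,
        bounds=list(zip(model.lb, model.ub)),
        method="highs",
        options={"primal_feasibility_tolerance": FEAS_TOL,
                 "dual_feasibility_tolerance": FEAS_TOL},
    )
    if res.status == 0:
        return FluxSolution(res.x, float(c @ res.x), "optimal")
    if res.status == 2:
        return FluxSolution(None, None, "infeasible")
    if res.status == 3:
        return FluxSolution(None, None, "unbounded")
    raise RuntimeError(f"LP solver failure: {res.message}")  # pragma: no cover


def fba(model: StoichModel) -> FluxSolution:
    """Maximize c^T v subject to S v = 0 and lb <= v <= ub.

    Degenerate alternate optima are inherent to LP: the returned vertex is
    solver-chosen; use :func:`fva` for uniqueness statements.
    """
    return _solve(model, model.c)


def fva(model: StoichModel, fraction: float = 1.0) -> dict[str, tuple[float, float]]:
    """Per-reaction flux range with the objective held at fraction * z*."""
    base = fba(model)
    if base.status != "optimal":
        raise ModelError(f"FVA requires an optimal FBA solution (got {base.status})")
    # c^T v >= f z*  <=>  -c^T v <= -f z*
    A = -model.c.reshape(1, -1)
    b = np.array([-fraction * base.objective])
    out = {}
    for i, rxn in enumerate(model.reactions):
        e = np.zeros(len(model.reactions))
        e[i] = 1.0
        lo = _solve(model, -e, A, b)
        hi = _solve(model, e, A, b)
        if lo.status != "optimal" or hi.status != "optimal":  # pragma: no cover
            raise ModelError(f"FVA subproblem for {rxn!r} not optimal")
        out[rxn] = (float(lo.v[i]), float(hi.v[i]))
    return out


def knockout(model: StoichModel, reaction: str) -> FluxSolution:
    """Fix one reaction to zero flux and re-solve the FBA problem."""
    m = model.copy()
    i = m.reaction_index(reaction)
    m.lb[i] = m.ub[i] = 0.0
    return fba(m)


def robustness(model: StoichModel, reaction: str,
               n_steps: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Objective response as one reaction is clamped across its FVA range.

    Returns (flux grid, objective values); infeasible grid points yield
    NaN.  For an LP the curve is concave in the clamped flux.
    """
    i = model.reaction_index(reaction)
    span = fva(model, fraction=0.0)[reaction]
    grid = np.linspace(span[0], span[1], n_steps)
    zs = np.empty(n_steps)
    for s, val in enumerate(grid):
        m = model.copy()
        m.lb[i] = m.ub[i] = val
        sol = fba(m)
        zs[s] = sol.objective if sol.status == "optimal" else np.nan
    return grid, zs
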