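"""Synthetic study data: block-correlated substance panels and toy networks.

The default specification mirrors the shape of a published *Arabidopsis
thaliana* ecotype panel: 64 metabolites, 37 enzyme activities and a
morphological target (fresh weight, "FW") measured across 50 ecotypes.
Substance profiles are built from per-condition latent pathway factors:

    z_s = rho * f_block + sqrt(1 - rho^2) * eps_s

with the noise component empirically orthogonalized against the factor so
the planted factor correlation is exact in-sample.  The morphological
target is regression-constructed from the profiles named in
``target_coupling`` so its planted marginal correlations are exact as
well; an infeasible coupling vector (non-positive-semidefinite implied
correlation matrix) raises a spec error.  Replicates add i.i.d. noise.

Ground-truth labels (block membership, planted edges, codes) travel in a
separate dictionary, never inside the Experiment, to keep downstream
pipeline stages honest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .experiment import Condition, Experiment, MappingTable, Substance, DATA_COLUMNS
from .graph import AttributedGraph, merge_networks


class SynthSpecError(ValueError):
    pass


DEFAULT_BLOCKS = [
    ("glycolysis", 12, 0.9),
    ("tca_cycle", 12, 0.9),
    ("amino_acids", 12, 0.9),
    ("sugar_metabolism", 12, 0.9),
]


@dataclass
class SynthSpec:
    n_metabolites: int = 64
    n_enzymes: int = 37
    n_morphological: int = 1
    n_conditions: int = 50
    n_replicates: int = 3
    blocks: list[tuple[str, int, float]] = field(default_factory=lambda: list(DEFAULT_BLOCKS))
    target_coupling: list[tuple[str, float]] = field(
        default_factory=lambda: [("met_049", 0.8), ("enz_001", -0.5)])
    noise_sd: float = 0.2
    missing_rate: float = 0.0
    seed: int = 1

    def __post_init__(self):
        if sum(b[1] for b in self.blocks) > self.n_metabolites + self.n_enzymes:
            raise SynthSpecError("block sizes exceed the metabolic substance count")
        if any(abs(b[2]) > 1 for b in self.blocks):
            raise SynthSpecError("block correlations must lie in [-1, 1]")
        if self.n_morphological < 1 and self.target_coupling:
            raise SynthSpecError("target coupling needs a morphological target")


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def _orthogonalize(v: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Residual of v after projection on the columns of basis, standardized."""
    q, _ = np.linalg.qr(basis)
    r = v - q @ (q.T @ v)
    if r.std() == 0:
        raise SynthSpecError("degenerate residual while planting correlations")
    return _standardize(r)


def generate_experiment(spec: SynthSpec) -> tuple[Experiment, dict]:
    """Draw a synthetic panel; returns (experiment, ground_truth)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_conditions

    mets = [f"met_{i + 1:03d}" for i in range(spec.n_metabolites)]
    enzs = [f"enz_{i + 1:03d}" for i in range(spec.n_enzymes)]
    morphs = (["FW"] + [f"morph_{i + 1:02d}" for i in range(1, spec.n_morphological)])[
        : spec.n_morphological]
    metabolic = mets + enzs

    # block membership: blocks consume metabolic substances front to back
    block_of: dict[str, str] = {}
    rho_of: dict[str, float] = {}
    cursor = 0
    for name, count, rho in spec.blocks:
        for s in metabolic[cursor:cursor + count]:
            block_of[s] = name
            rho_of[s] = rho
        cursor += count

    factors = {name: _standardize(rng.standard_normal(n))
               for name, _c, _r in spec.blocks}
    profiles: dict[str, np.ndarray] = {}
    for s in metabolic:
        eps = rng.standard_normal(n)
        if s in block_of:
            f = factors[block_of[s]]
            rho = rho_of[s]
            eps = _orthogonalize(eps, f.reshape(-1, 1))
            profiles[s] = rho * f + math.sqrt(1 - rho * rho) * eps
        else:
            profiles[s] = _standardize(eps)

    # morphological target: exact planted marginal correlations
    couplings = list(spec.target_coupling)
    if morphs and couplings:
        names = [s for s, _r in couplings]
        unknown = [s for s in names if s not in profiles]
        if unknown:
            raise SynthSpecError(f"target coupling names unknown substances {unknown}")
        # coupled substances outside blocks are independent by design; make
        # their realized profiles empirically uncorrelated so feasibility
        # does not drift with the sampling of a finite condition panel
        done: list[str] = []
        for s in names:
            if s not in block_of and done:
                basis = np.column_stack([profiles[d] for d in done])
                profiles[s] = _orthogonalize(profiles[s], basis)
            done.append(s)
        z = np.column_stack([profiles[s] for s in names])
        sigma = np.corrcoef(z, rowvar=False) if z.shape[1] > 1 else np.ones((1, 1))
        r = np.array([r for _s, r in couplings])
        w = np.linalg.solve(sigma, r)
        explained = float(r @ w)
        if explained > 1 + 1e-9:
            raise SynthSpecError(
                f"target coupling implies a non-PSD correlation matrix "
                f"(explained variance {explained:.3f} > 1)")
        eps = _orthogonalize(rng.standard_normal(n), z)
        profiles[morphs[0]] = z @ w + math.sqrt(max(1 - explained, 0.0)) * eps
    for s in morphs[0 if not couplings else 1:]:
        if s not in profiles:
            profiles[s] = _standardize(rng.standard_normal(n))

    substances = (
        [Substance(s, "metabolite", "nmol/g FW") for s in mets]
        + [Substance(s, "enzyme", "U/g FW") for s in enzs]
        + [Substance(s, "morphological", "g") for s in morphs]
    )
    conditions = [Condition(f"ecotype_{i + 1:02d}", species="Arabidopsis thaliana",
                            genotype=f"ecotype_{i + 1:02d}")
                  for i in range(n)]
    cond_names = [c.name for c in conditions]

    base = {s.name: rng.uniform(5.0, 50.0) for s in substances}
    scale = {s.name: rng.uniform(0.5, 5.0) for s in substances}
    records = []
    for s in substances:
        prof = base[s.name] + scale[s.name] * profiles[s.name]
        for ci, cond in enumerate(cond_names):
            for rep in range(1, spec.n_replicates + 1):
                if spec.missing_rate and rng.random() < spec.missing_rate:
                    continue
                v = prof[ci] + spec.noise_sd * scale[s.name] * rng.standard_normal()
                records.append((s.name, cond, 0.0, "", rep, float(v)))
    exp = Experiment(substances, conditions,
                     pd.DataFrame(records, columns=DATA_COLUMNS),
                     meta={"name": "synthetic ecotype panel",
                           "species": "Arabidopsis thaliana",
                           "seed": spec.seed})

    codes = ({s: f"M{i + 1:03d}" for i, s in enumerate(mets)}
             | {s: f"E{i + 1:03d}" for i, s in enumerate(enzs)})
    planted_edges = sorted(
        {tuple(sorted((a, b)))
         for blk in {v for v in block_of.values()}
         for a in [s for s in metabolic if block_of.get(s) == blk]
         for b in [s for s in metabolic if block_of.get(s) == blk]
         if a != b}
    )
    truth = {
        "blocks": block_of,
        "block_rho": rho_of,
        "target": morphs[0] if morphs else None,
        "couplings": {s: r for s, r in couplings} if morphs else {},
        "planted_edges": planted_edges,
        "codes": codes,
        "substances": {"metabolite": mets, "enzyme": enzs, "morphological": morphs},
    }
    return exp, truth


def generate_mapping_table(truth: dict) -> MappingTable:
    """Synonym table linking network node codes to substance names."""
    return MappingTable([(code, [name]) for name, code in sorted(truth["codes"].items())])


# ---------------------------------------------------------------------------
# toy networks


def generate_network(kind: str, size: int = 3) -> AttributedGraph:
    """Small bipartite metabolic graphs with SBGN classes, stoichiometry 1."""
    if size < 2:
        raise ValueError("size must be >= 2")
    g = AttributedGraph()
    if kind == "chain":
        mets = [g.add_node(label=f"M{i + 1}", sbgn_class="simple_chemical")
                for i in range(size)]
        for i in range(size - 1):
            p = g.add_node(label=f"R{i + 1}", sbgn_class="process")
            g.add_edge(mets[i], p, weight=1)
            g.add_edge(p, mets[i + 1], weight=1)
    elif kind == "cycle":
        mets = [g.add_node(label=f"M{i + 1}", sbgn_class="simple_chemical")
                for i in range(size)]
        for i in range(size):
            p = g.add_node(label=f"R{i + 1}", sbgn_class="process")
            g.add_edge(mets[i], p, weight=1)
            g.add_edge(p, mets[(i + 1) % size], weight=1)
    elif kind == "branched":
        src = g.add_node(label="S", sbgn_class="simple_chemical")
        hub = g.add_node(label="H", sbgn_class="simple_chemical")
        p0 = g.add_node(label="R0", sbgn_class="process")
        g.add_edge(src, p0, weight=1)
        g.add_edge(p0, hub, weight=1)
        for i in range(size - 1):
            sink = g.add_node(label=f"T{i + 1}", sbgn_class="simple_chemical")
            p = g.add_node(label=f"R{i + 1}", sbgn_class="process")
            g.add_edge(hub, p, weight=1)
            g.add_edge(p, sink, weight=1)
    elif kind == "two_pathways":
        g1 = generate_network("chain", size)
        g2 = generate_network("chain", size)
        for n in g1.nodes:
            g1.set_attr("node", n, "pathway", "pw1")
        for n in g2.nodes:
            g2.set_attr("node", n, "pathway", "pw2")
            g2.set_label(n, g2.label(n).replace("M", "N").replace("R", "Q"))
        # share one metabolite: last of pw1 == first of pw2
        shared = [n for n in g2.nodes if g2.label(n) == "N1"][0]
        g2.set_label(shared, f"M{size}")
        return merge_networks([g1, g2], key="label", classes=["simple_chemical"])
    else:
        raise ValueError(f"unknown network kind {kind!r}")
    return g


def generate_pathway_network(truth: dict) -> AttributedGraph:
    """SBGN-style network matching the synthetic panel's ground truth.

    Each pathway block becomes a chain of its metabolites (nodes labeled by
    short codes, the mapping table restores substance names); enzymes are
    attached to the processes they catalyze, round-robin.  Unblocked
    metabolites form an extra "other" pathway.  Morphological parameters
    are deliberately absent - they enter as created nodes during mapping.
    """
    codes = truth["codes"]
    blocks = truth["blocks"]
    mets = truth["substances"]["metabolite"]
    enzs = truth["substances"]["enzyme"]

    pathways: dict[str, list[str]] = {}
    for s in mets:
        pathways.setdefault(blocks.get(s, "other"), []).append(s)
    enz_by_block: dict[str, list[str]] = {}
    for s in enzs:
        enz_by_block.setdefault(blocks.get(s, "other"), []).append(s)

    graphs = []
    for pw in sorted(pathways):
        members = pathways[pw]
        g = AttributedGraph()
        met_nodes = []
        for s in members:
            nid = g.add_node(label=codes[s], sbgn_class="simple_chemical")
            g.set_attr("node", nid, "pathway", pw)
            met_nodes.append(nid)
        enzymes = enz_by_block.get(pw, [])
        procs = []
        for i in range(len(met_nodes) - 1):
            p = g.add_node(label=f"{pw}_r{i + 1}", sbgn_class="process")
            g.set_attr("node", p, "pathway", pw)
            g.add_edge(met_nodes[i], p, weight=1)
            g.add_edge(p, met_nodes[i + 1], weight=1)
            procs.append(p)
        for i, s in enumerate(enzymes):
            nid = g.add_node(label=codes[s], sbgn_class="macromolecule")
            g.set_attr("node", nid, "pathway", pw)
            if procs:
                g.add_edge(nid, procs[i % len(procs)], interaction="catalysis")
        graphs.append(g)
    # enzymes of blocks without metabolite members (e.g. all-enzyme "other")
    placed = {s for pw in pathways for s in enz_by_block.get(pw, [])}
    rest = [s for s in enzs if s not in placed]
    if rest:
        g = AttributedGraph()
        for s in rest:
            nid = g.add_node(label=codes[s], sbgn_class="macromolecule")
            g.set_attr("node", nid, "pathway", blocks.get(s, "other"))
        graphs.append(g)
    return merge_networks(graphs, key="label", classes=["simple_chemical"])
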