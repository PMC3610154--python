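import numpy as np
import pandas as pd
import pytest

from omicnet.experiment import Condition, Experiment, Substance, DATA_COLUMNS
from omicnet.graph import AttributedGraph


@pytest.fixture
def sugar_graph():
    """Tiny SBGN-style network: Glc --HXK--> pyruvate-side chain."""
    g = AttributedGraph()
    glc = g.add_node(node_id="glc", label="Glc", sbgn_class="simple_chemical")
    hxk = g.add_node(node_id="hxk", label="HXK", sbgn_class="macromolecule")
    rxn = g.add_node(node_id="r1", label="r1", sbgn_class="process")
    g.add_edge(glc, rxn, weight=1)
    g.add_edge(hxk, rxn, interaction="catalysis")
    return g


@pytest.fixture
def small_experiment():
    subs = [
        Substance("Glucose", "metabolite", "mM", alt_ids=("Glc",)),
        Substance("HXK", "enzyme", "U"),
        Substance("FW", "morphological", "g"),
    ]
    conds = [Condition("c1"), Condition("c2"), Condition("c3"), Condition("c4")]
    rec = []
    base = {"Glucose": [1.0, 2.0, 3.0, 4.0],
            "HXK": [2.0, 4.0, 6.0, 8.0],
            "FW": [4.0, 3.0, 2.0, 1.0]}
    for s in subs:
        for ci, c in enumerate(conds):
            for rep in (1, 2):
                rec.append((s.name, c.name, 0.0, "", rep, base[s.name][ci]))
    return Experiment(subs, conds, pd.DataFrame(rec, columns=DATA_COLUMNS))


def random_attributed_graph(seed: int, max_nodes: int = 8) -> AttributedGraph:
    """Random multigraph with adversarial attribute keys and mixed values."""
    rng = np.random.default_rng(seed)
    g = AttributedGraph()
    n = int(rng.integers(1, max_nodes + 1))
    keys = ["weight", "graphics.fill", "my attr.with dots", "vKodd", "label2",
            "unicode-µmol", "mapping.Glc 6P.c1.0.0", "_under", "123num"]
    values = ["txt", "", 3, -7, 2.5, True, False, "vB:tricky", "line\nbreak",
              "#ff0000", 1.0e-9]
    nodes = []
    for i in range(n):
        nid = g.add_node(label=f"node {i}",
                         sbgn_class=str(rng.choice(["simple_chemical",
                                                    "macromolecule", "process",
                                                    "unspecified"])))
        nodes.append(nid)
        for _ in range(int(rng.integers(0, 4))):
            g.set_attr("node", nid, str(rng.choice(keys)),
                       values[int(rng.integers(len(values)))])
    for _ in range(int(rng.integers(0, 2 * n))):
        u, v = rng.choice(nodes, 2)
        e = g.add_edge(str(u), str(v))
        for _ in range(int(rng.integers(0, 3))):
            g.set_attr("edge", e, str(rng.choice(keys)),
                       values[int(rng.integers(len(values)))])
    if rng.random() < 0.5:
        g.graph_attrs["experiment name"] = "run 1"
        g.graph_attrs["count"] = int(rng.integers(100))
    return g
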