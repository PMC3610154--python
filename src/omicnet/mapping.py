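"""Integration of experiment data into networks (data mapping).

A substance is attached to a node when one of its names (name or synonym)
equals one of the node's names (label or alternative identifier) and the
node's SBGN class agrees with the class rule for the substance kind
(metabolite data goes to simple-chemical glyphs, enzyme activities to
macromolecule glyphs).  Substances without a matching node - typically
morphological parameters such as fresh weight - can be added as new nodes.

Mapped values live under the node-attribute path
``mapping.<substance>.<condition>.<time>.<replicate>`` (components
percent-escaped), so a GML/GraphML round trip preserves every measurement
bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .experiment import (Condition, Experiment, MappingTable, Substance,
                         DATA_COLUMNS)
from .graph import AttributedGraph, attr_path, split_attr_path

log = logging.getLogger(__name__)

MAPPING_PREFIX = "mapping"
META_PREFIX = "mappingmeta"


def normalize_name(name: str) -> str:
    return name.strip().casefold()


@dataclass
class MappingReport:
    """Outcome of a data-mapping run: how every substance was resolved."""

    mapped: list[tuple[str, str]] = field(default_factory=list)
    unmapped_substances: list[str] = field(default_factory=list)
    created_nodes: list[str] = field(default_factory=list)
    ambiguous: list[tuple[str, list[str]]] = field(default_factory=list)

    @property
    def mapped_substances(self) -> list[str]:
        return sorted({s for s, _ in self.mapped})

    def counts(self) -> dict[str, int]:
        created_subs = len(self.created_nodes)
        return {
            "mapped": len(self.mapped_substances) - created_subs,
            "unmapped": len(self.unmapped_substances),
            "created": created_subs,
        }


def enrich_identifiers(g: AttributedGraph, table: MappingTable,
                       case_sensitive: bool = False) -> AttributedGraph:
    """Append synonyms from a mapping table to matching nodes' alt_ids."""
    out = g.copy()
    norm = (lambda s: s.strip()) if case_sensitive else normalize_name
    index: dict[str, list[str]] = {}
    for n in out.nodes:
        for name in out.names(n):
            index.setdefault(norm(name), []).append(n)
    unused = 0
    for primary, synonyms in table.rows:
        nodes = index.get(norm(primary), [])
        if not nodes:
            unused += 1
            continue
        for n in nodes:
            for syn in synonyms:
                out.add_alt_id(n, syn)
    if unused:
        log.info("enrich_identifiers: %d mapping-table rows matched no node", unused)
    return out


def map_experiment(
    g: AttributedGraph,
    e: Experiment,
    class_rule: dict[str, str] | None = None,
    create_missing: bool = True,
    case_sensitive: bool = False,
) -> tuple[AttributedGraph, MappingReport]:
    """Attach the measurement tensor to network nodes by identifier match.

    ``class_rule`` maps substance kinds to admissible SBGN classes and must
    cover every kind present in the experiment.  A substance matching more
    than one admissible node (split cofactor nodes, for example) is mapped
    to ALL candidates and recorded as ambiguous.
    """
    if class_rule is None:
        class_rule = {"metabolite": "simple_chemical", "enzyme": "macromolecule",
                      "morphological": "unspecified", "gene": "macromolecule",
                      "other": "unspecified"}
    kinds_present = {s.kind for s in e.substances}
    uncovered = kinds_present - set(class_rule)
    if uncovered:
        raise ValueError(f"class_rule does not cover substance kinds {sorted(uncovered)}")

    out = g.copy()
    report = MappingReport()
    norm = (lambda s: s.strip()) if case_sensitive else normalize_name
    index: dict[str, list[str]] = {}
    for n in out.nodes:
        for name in out.names(n):
            index.setdefault(norm(name), []).append(n)

    # deterministic and order-independent: substances processed sorted by name
    for sub in sorted(e.substances, key=lambda s: s.name):
        wanted_class = class_rule[sub.kind]
        candidates: list[str] = []
        for name in (sub.name, *sub.alt_ids):
            for n in index.get(norm(name), []):
                if out.sbgn_class(n) == wanted_class and n not in candidates:
                    candidates.append(n)
        if not candidates:
            if not create_missing:
                report.unmapped_substances.append(sub.name)
                continue
            nid = out.add_node(label=sub.name, sbgn_class=wanted_class)
            for syn in sub.alt_ids:
                out.add_alt_id(nid, syn)
            report.created_nodes.append(nid)
            candidates = [nid]
        elif len(candidates) > 1:
            report.ambiguous.append((sub.name, sorted(candidates)))
        for n in sorted(candidates):
            _write_measurements(out, n, sub, e)
            report.mapped.append((sub.name, n))

    out.graph_attrs["mapping_conditions"] = "|".join(e.condition_names())
    return out, report


def _write_measurements(g: AttributedGraph, node: str, sub: Substance,
                        e: Experiment) -> None:
    sel = e.data[e.data["substance"] == sub.name]
    for row in sel.itertuples():
        path = attr_path(MAPPING_PREFIX, sub.name, row.condition,
                         repr(row.time), str(row.replicate))
        g.set_attr("node", node, path, float(row.value))
        if row.time_unit:
            g.set_attr("node", node,
                       attr_path(META_PREFIX, sub.name, "time_unit"), row.time_unit)
    g.set_attr("node", node, attr_path(META_PREFIX, sub.name, "kind"), sub.kind)
    if sub.unit:
        g.set_attr("node", node, attr_path(META_PREFIX, sub.name, "unit"), sub.unit)
    if sub.alt_ids:
        g.set_attr("node", node, attr_path(META_PREFIX, sub.name, "alt_ids"),
                   "|".join(sub.alt_ids))
    subs = g.get_attr("node", node, "mapping_substances", "")
    names = [s for s in subs.split("|") if s]
    if sub.name not in names:
        names.append(sub.name)
    g.set_attr("node", node, "mapping_substances", "|".join(names))


# ---------------------------------------------------------------------------
# reading mapped data back out of a graph


def mapped_nodes(g: AttributedGraph) -> list[str]:
    return [n for n in g.nodes if g.get_attr("node", n, "mapping_substances")]


def node_measurements(g: AttributedGraph, node: str) -> pd.DataFrame:
    """Long-form measurements carried by one node."""
    records = []
    for path, value in g.attrs_under("node", node, MAPPING_PREFIX).items():
        parts = split_attr_path(path)
        if len(parts) != 5:
            continue
        _, sub, cond, t, rep = parts
        unit_path = attr_path(META_PREFIX, sub, "time_unit")
        records.append((sub, cond, float(t),
                        g.get_attr("node", node, unit_path, ""), int(rep), float(value)))
    return pd.DataFrame(records, columns=DATA_COLUMNS)


def node_profiles(g: AttributedGraph,
                  conditions: list[str] | None = None) -> pd.DataFrame:
    """Mapped nodes x conditions matrix of replicate means.

    The observation axis (column order) is the condition order recorded at
    mapping time, so profiles are comparable across nodes.
    """
    if conditions is None:
        raw = g.graph_attrs.get("mapping_conditions", "")
        conditions = [c for c in str(raw).split("|") if c]
    rows = {}
    for n in mapped_nodes(g):
        m = node_measurements(g, n)
        if m.empty:
            continue
        means = m.groupby("condition")["value"].mean()
        rows[n] = means
    prof = pd.DataFrame(rows).T
    if not conditions:
        conditions = sorted(prof.columns)
    return prof.reindex(columns=conditions)


def export_mapped_data(g: AttributedGraph, path) -> Path:
    """Dump all mapped measurements to an XLSX (or CSV) sheet.

    One row per (node, substance, condition, time, replicate); the file can
    be re-imported with :func:`omicnet.experiment.read_csv_long` (CSV) or
    pandas (XLSX) and re-mapped, reproducing the same node attributes.
    """
    path = Path(path)
    frames = []
    for n in mapped_nodes(g):
        m = node_measurements(g, n)
        m.insert(0, "node", n)
        m.insert(2, "kind", [
            g.get_attr("node", n, attr_path(META_PREFIX, s, "kind"), "other")
            for s in m["substance"]])
        m.insert(3, "unit", [
            g.get_attr("node", n, attr_path(META_PREFIX, s, "unit"), "")
            for s in m["substance"]])
        m.insert(4, "alt_ids", [
            g.get_attr("node", n, attr_path(META_PREFIX, s, "alt_ids"), "")
            for s in m["substance"]])
        frames.append(m)
    cols = ["node", "substance", "kind", "unit", "alt_ids", "condition",
            "time", "time_unit", "replicate", "value"]
    table = (pd.concat(frames, ignore_index=True)[cols]
             .sort_values(["node", "substance", "condition", "time", "replicate"])
             .reset_index(drop=True)
             if frames else pd.DataFrame(columns=cols))
    if path.suffix.lower() == ".csv":
        table.to_csv(path, index=False)
    else:
        table.to_excel(path, index=False, sheet_name="mapped_data")
    return path
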