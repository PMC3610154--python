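"""Structured experiment data: substances x conditions x times x replicates.

The central container mirrors how plant-phenotyping panels are shaped: a
set of measured substances (metabolites, enzyme activities, morphological
parameters), a set of conditions (ecotypes, genotypes, treatments), each
sampled at time points with several replicates.  Measurements are held in
long form; missing cells are simply absent rows, never zeros, and all
downstream statistics use pairwise-complete observations.

The XLS template dialect (self-defined, documented in the methods note):

* sheet ``meta``  - two-column key/value rows (experiment name, species, ...)
* sheet ``data``  - header rows 1-4 hold condition name / time value /
  time unit / replicate index for every measurement column (from column D);
  column A is the substance name, B its kind, C its unit; the measurement
  matrix starts at row 5.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SUBSTANCE_KINDS = ("metabolite", "enzyme", "morphological", "gene", "other")

DATA_COLUMNS = ["substance", "condition", "time", "time_unit", "replicate", "value"]


class TemplateError(ValueError):
    """Workbook does not follow the template dialect."""


class ConfigurationError(ValueError):
    """A declared column/field is missing or inconsistent."""


@dataclass(frozen=True)
class Substance:
    name: str
    kind: str = "other"
    unit: str = ""
    alt_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.name:
            raise ValueError("substance name must be non-empty")
        if self.kind not in SUBSTANCE_KINDS:
            raise ValueError(f"unknown substance kind {self.kind!r}")
        if len(set(self.alt_ids)) != len(self.alt_ids):
            raise ValueError(f"duplicate alt_ids for substance {self.name!r}")


@dataclass(frozen=True)
class Condition:
    name: str
    species: str = ""
    genotype: str = ""
    treatment: str = ""


class Experiment:
    """Measurement tensor plus metadata, stored in long form."""

    def __init__(
        self,
        substances: list[Substance],
        conditions: list[Condition],
        data: pd.DataFrame | None = None,
        meta: dict | None = None,
    ):
        names = [s.name for s in substances]
        if len(set(names)) != len(names):
            raise ValueError("duplicate substance names")
        cnames = [c.name for c in conditions]
        if len(set(cnames)) != len(cnames):
            raise ValueError("duplicate condition names")
        self.substances = list(substances)
        self.conditions = list(conditions)
        self.meta = dict(meta or {})
        if data is None:
            data = pd.DataFrame(columns=DATA_COLUMNS)
        missing = set(DATA_COLUMNS) - set(data.columns)
        if missing:
            raise ValueError(f"data frame lacks columns {sorted(missing)}")
        bad_sub = set(data["substance"]) - set(names)
        if bad_sub:
            raise ValueError(f"measurements reference undeclared substances {sorted(bad_sub)}")
        bad_cond = set(data["condition"]) - set(cnames)
        if bad_cond:
            raise ValueError(f"measurements reference undeclared conditions {sorted(bad_cond)}")
        dup = data.duplicated(subset=["substance", "condition", "time", "replicate"])
        if dup.any():
            raise ValueError("duplicate replicate index within (substance, condition, time)")
        self.data = data.reset_index(drop=True)[DATA_COLUMNS].astype(
            {"substance": str, "condition": str, "time": float,
             "time_unit": str, "replicate": int, "value": float}
        )

    # -- lookups ---------------------------------------------------------

    def substance(self, name: str) -> Substance:
        for s in self.substances:
            if s.name == name:
                return s
        raise KeyError(name)

    def substance_names(self, kind: str | None = None) -> list[str]:
        return [s.name for s in self.substances if kind is None or s.kind == kind]

    def condition_names(self) -> list[str]:
        return [c.name for c in self.conditions]

    def n_measurements(self) -> int:
        return len(self.data)

    def times(self) -> list[float]:
        return sorted(self.data["time"].unique())

    # -- analysis helpers ------------------------------------------------

    def profile_matrix(self, kinds: tuple[str, ...] | None = None) -> pd.DataFrame:
        """Substances x conditions matrix of replicate means (NaN = missing).

        This is the observation matrix used for correlation and clustering:
        one value per (substance, condition), averaging replicates and time
        points.  Column order follows the declared condition order.
        """
        subs = [s.name for s in self.substances if kinds is None or s.kind in kinds]
        piv = self.data.pivot_table(index="substance", columns="condition",
                                    values="value", aggfunc="mean")
        piv = piv.reindex(index=subs, columns=self.condition_names())
        return piv

    def __eq__(self, other) -> bool:
        if not isinstance(other, Experiment):
            return NotImplemented
        # declaration order is presentation, not content
        if sorted(self.substances, key=lambda s: s.name) != \
                sorted(other.substances, key=lambda s: s.name):
            return False
        if sorted(self.conditions, key=lambda c: c.name) != \
                sorted(other.conditions, key=lambda c: c.name):
            return False
        key = ["substance", "condition", "time", "replicate"]
        a = self.data.sort_values(key).reset_index(drop=True)
        b = other.data.sort_values(key).reset_index(drop=True)
        if len(a) != len(b) or not a.drop(columns="value").equals(b.drop(columns="value")):
            return False
        # XLSX numeric cells carry 16 significant digits; values are compared
        # to that precision rather than bit-exactly
        return bool(np.allclose(a["value"], b["value"], rtol=1e-14, atol=0.0))

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<Experiment {len(self.substances)} substances x "
                f"{len(self.conditions)} conditions, {len(self.data)} measurements>")

    # -- JSON serialization (internal exchange format) -------------------

    def to_json(self, path=None) -> str:
        obj = {
            "meta": self.meta,
            "substances": [vars(s) | {"alt_ids": list(s.alt_ids)} for s in self.substances],
            "conditions": [vars(c) for c in self.conditions],
            "measurements": self.data.to_dict(orient="records"),
        }
        text = json.dumps(obj, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "Experiment":
        if isinstance(source, Path) or (isinstance(source, str)
                                        and not source.lstrip().startswith("{")):
            obj = json.loads(Path(source).read_text())
        else:
            obj = json.loads(source)
        subs = [Substance(name=s["name"], kind=s["kind"], unit=s["unit"],
                          alt_ids=tuple(s["alt_ids"])) for s in obj["substances"]]
        conds = [Condition(**c) for c in obj["conditions"]]
        df = pd.DataFrame(obj["measurements"], columns=DATA_COLUMNS)
        return cls(subs, conds, df, obj.get("meta"))


# ---------------------------------------------------------------------------
# XLS template


def write_template(e: Experiment, path) -> Path:
    from openpyxl import Workbook

    wb = Workbook()
    ws = wb.active
    ws.title = "meta"
    ws.append(["key", "value"])
    for k, v in sorted(e.meta.items()):
        ws.append([k, v])

    ws = wb.create_sheet("conditions")
    ws.append(["name", "species", "genotype", "treatment"])
    for c in e.conditions:
        ws.append([c.name, c.species, c.genotype, c.treatment])

    ws = wb.create_sheet("data")
    # sample columns: one per (condition, time, time_unit, replicate)
    samples = (
        e.data[["condition", "time", "time_unit", "replicate"]]
        .drop_duplicates()
        .sort_values(["condition", "time", "replicate"])
        .values.tolist()
    )
    cond_order = {c.name: i for i, c in enumerate(e.conditions)}
    samples.sort(key=lambda s: (cond_order.get(s[0], 1 << 30), s[1], s[3]))
    ws.append(["substance", "kind", "unit"] + [s[0] for s in samples])
    ws.append(["", "", "time"] + [s[1] for s in samples])
    ws.append(["", "", "time unit"] + [s[2] for s in samples])
    ws.append(["", "", "replicate"] + [int(s[3]) for s in samples])
    lut = {(r.substance, r.condition, r.time, r.replicate): r.value
           for r in e.data.itertuples()}
    for s in e.substances:
        row: list = [s.name, s.kind, s.unit]
        for cond, t, tu, rep in samples:
            row.append(lut.get((s.name, cond, t, rep)))
        ws.append(row)
    wb.save(path)
    return Path(path)


def read_template(path) -> Experiment:
    """Parse the structured XLS/XLSX template into an :class:`Experiment`."""
    from openpyxl import load_workbook

    wb = load_workbook(path, read_only=True, data_only=True)
    if "data" not in wb.sheetnames:
        raise TemplateError(f"{path}: workbook has no 'data' sheet")
    meta: dict = {}
    if "meta" in wb.sheetnames:
        for row in wb["meta"].iter_rows(min_row=2, values_only=True):
            if row and row[0] is not None:
                meta[str(row[0])] = row[1]
    has_cond_sheet = "conditions" in wb.sheetnames
    cond_rows = (list(wb["conditions"].iter_rows(values_only=True))
                 if has_cond_sheet else [])
    rows = list(wb["data"].iter_rows(values_only=True))
    wb.close()
    if len(rows) < 4:
        raise TemplateError(f"{path}: data sheet needs 4 header rows")
    head_cond, head_time, head_unit, head_rep = rows[0], rows[1], rows[2], rows[3]
    n_cols = len(head_cond)
    samples = []
    for j in range(3, n_cols):
        cond = head_cond[j]
        if cond is None:
            continue
        t = float(head_time[j]) if head_time[j] is not None else 0.0
        tu = str(head_unit[j]) if head_unit[j] is not None else ""
        rep = int(head_rep[j]) if head_rep[j] is not None else 1
        samples.append((j, str(cond), t, tu, rep))

    substances: list[Substance] = []
    seen: set[str] = set()
    records = []
    skipped = 0
    for ri, row in enumerate(rows[4:], start=5):
        if row is None or row[0] is None:
            continue
        name = str(row[0])
        if name in seen:
            raise TemplateError(f"{path}: duplicate substance row {name!r} (row {ri})")
        seen.add(name)
        kind = str(row[1]) if len(row) > 1 and row[1] else "other"
        unit = str(row[2]) if len(row) > 2 and row[2] else ""
        substances.append(Substance(name=name, kind=kind, unit=unit))
        for (j, cond, t, tu, rep) in samples:
            v = row[j] if j < len(row) else None
            if v is None or (isinstance(v, str) and not v.strip()):
                continue
            try:
                v = float(v)
            except (TypeError, ValueError):
                skipped += 1
                log.warning("%s: row %d column %d: non-numeric cell %r skipped",
                            path, ri, j + 1, v)
                continue
            records.append((name, cond, t, tu, rep, v))
    if skipped:
        log.info("%s: skipped %d non-numeric cells", path, skipped)
    cond_meta: dict[str, Condition] = {}
    if has_cond_sheet:
        for row in cond_rows[1:]:
            if row and row[0] is not None:
                vals = [str(c) if c is not None else "" for c in row[:4]]
                vals += [""] * (4 - len(vals))
                cond_meta[vals[0]] = Condition(*vals)
    conditions = []
    seen_c: set[str] = set()
    for (_, cond, *_rest) in samples:
        if cond not in seen_c:
            seen_c.add(cond)
            conditions.append(cond_meta.get(cond, Condition(name=cond)))
    df = pd.DataFrame(records, columns=DATA_COLUMNS)
    return Experiment(substances, conditions, df, meta)


# ---------------------------------------------------------------------------
# long CSV


def read_csv_long(path, column_map: dict, defaults: dict | None = None) -> Experiment:
    """Fold a long-format CSV into an Experiment.

    ``column_map`` maps roles to column names; ``substance`` and ``value``
    are required, ``condition``/``time``/``time_unit``/``replicate``/
    ``kind``/``unit`` optional.  ``defaults`` supplies constant metadata for
    roles without a column (manual enrichment of plain CSV exports).
    """
    defaults = dict(defaults or {})
    if "substance" not in column_map or "value" not in column_map:
        raise ConfigurationError("column_map must declare 'substance' and 'value' columns")
    df = pd.read_csv(path)
    for role, col in column_map.items():
        if col not in df.columns:
            raise ConfigurationError(f"declared column {col!r} for role {role!r} "
                                     f"not present in {path}")

    def series(role, default):
        col = column_map.get(role)
        if col is not None:
            return df[col]
        return pd.Series([defaults.get(role, default)] * len(df))

    out = pd.DataFrame({
        "substance": df[column_map["substance"]].astype(str),
        "condition": series("condition", "default").astype(str),
        "time": pd.to_numeric(series("time", 0.0)),
        "time_unit": series("time_unit", "").astype(str),
        "replicate": series("replicate", 1).astype(int),
        "value": pd.to_numeric(df[column_map["value"]], errors="coerce"),
    })
    n_bad = out["value"].isna().sum()
    if n_bad:
        log.warning("%s: dropped %d non-numeric measurement cells", path, n_bad)
        out = out.dropna(subset=["value"])
    if "replicate" not in column_map:
        # synthesize replicate indices per (substance, condition, time)
        out["replicate"] = out.groupby(["substance", "condition", "time"]).cumcount() + 1

    kind_col, unit_col = column_map.get("kind"), column_map.get("unit")
    alt_col = column_map.get("alt_ids")
    substances = []
    for name, grp in out.groupby("substance", sort=True):
        idx = grp.index[0]
        kind = str(df[kind_col][idx]) if kind_col else defaults.get("kind", "other")
        unit = str(df[unit_col][idx]) if unit_col else defaults.get("unit", "")
        if unit == "nan":
            unit = ""
        alt_raw = str(df[alt_col][idx]) if alt_col else ""
        alts = tuple(a for a in alt_raw.split("|") if a and a != "nan")
        substances.append(Substance(name=str(name), kind=kind, unit=unit,
                                    alt_ids=alts))
    conditions = [Condition(name=c,
                            species=str(defaults.get("species", "")))
                  for c in pd.unique(out["condition"])]
    meta = {k: v for k, v in defaults.items()
            if k in ("name", "coordinator", "species")}
    return Experiment(substances, conditions, out, meta)


# ---------------------------------------------------------------------------
# mapping tables


@dataclass
class MappingTable:
    """Synonym list: primary name -> additional names (first column + rest)."""

    rows: list[tuple[str, list[str]]] = field(default_factory=list)

    def __post_init__(self):
        names = [p for p, _ in self.rows]
        if len(set(names)) != len(names):
            dups = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate primary names in mapping table: {dups}")

    def synonyms(self, primary: str) -> list[str]:
        for p, syns in self.rows:
            if p == primary:
                return syns
        return []

    def __len__(self) -> int:
        return len(self.rows)


def read_mapping_table(path) -> MappingTable:
    """Read a 2+-column XLS/CSV synonym table (primary name, synonyms...)."""
    path = Path(path)
    if path.suffix.lower() in (".xls", ".xlsx"):
        from openpyxl import load_workbook
        wb = load_workbook(path, read_only=True, data_only=True)
        raw = [list(r) for r in wb[wb.sheetnames[0]].iter_rows(values_only=True)]
        wb.close()
    else:
        raw = [line.split(",") for line in path.read_text().splitlines() if line.strip()]
    rows = []
    max_cols = max((len(r) for r in raw), default=0)
    if max_cols < 2:
        raise ValueError(f"{path}: no synonym columns (need >= 2 columns)")
    for r in raw:
        if not r or r[0] is None or str(r[0]).strip() == "":
            continue
        primary = str(r[0]).strip()
        syns = [str(c).strip() for c in r[1:] if c is not None and str(c).strip()]
        rows.append((primary, syns))
    return MappingTable(rows)


# ---------------------------------------------------------------------------
# replicate statistics


def summarize(e: Experiment, substance: str, condition: str) -> pd.DataFrame:
    """Per-time-point replicate statistics: n, mean, sd, sem.

    ``n`` counts present values only; sd/sem are NaN for n < 2 (undefined
    rather than zero).  Returns an empty frame when nothing was measured.
    """
    if substance not in {s.name for s in e.substances}:
        raise KeyError(f"undeclared substance {substance!r}")
    if condition not in {c.name for c in e.conditions}:
        raise KeyError(f"undeclared condition {condition!r}")
    sel = e.data[(e.data["substance"] == substance) & (e.data["condition"] == condition)]
    if sel.empty:
        return pd.DataFrame(columns=["n", "mean", "sd", "sem"], dtype=float)
    g = sel.groupby("time")["value"]
    out = pd.DataFrame({"n": g.count(), "mean": g.mean(), "sd": g.std(ddof=1)})
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out
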