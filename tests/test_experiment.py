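"""Experiment container, XLS template dialect, CSV import, statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from omicnet.experiment import (Condition, ConfigurationError, Experiment,
                                MappingTable, Substance, TemplateError,
                                DATA_COLUMNS, read_csv_long, read_mapping_table,
                                read_template, summarize, write_template)


def build_experiment(values=None, n_reps=3):
    subs = [Substance("Glc", "metabolite", "mM"), Substance("Fru", "metabolite", "mM")]
    conds = [Condition("c1"), Condition("c2")]
    rec = []
    for s in subs:
        for c in conds:
            for r in range(1, n_reps + 1):
                v = values.get((s.name, c.name, r)) if values else float(r)
                if v is not None:
                    rec.append((s.name, c.name, 0.0, "", r, v))
    return Experiment(subs, conds, pd.DataFrame(rec, columns=DATA_COLUMNS))


class TestTemplate:
    def test_full_tensor_counts(self, tmp_path):
        e = build_experiment()
        p = tmp_path / "exp.xlsx"
        write_template(e, p)
        e2 = read_template(p)
        assert e2.n_measurements() == 2 * 2 * 3 == 12
        assert e == e2

    def test_blank_cell_is_absent_not_zero(self, tmp_path):
        e = build_experiment(values={("Glc", "c1", 1): None} |
                             {(s, c, r): float(r) for s in ("Glc", "Fru")
                              for c in ("c1", "c2") for r in (1, 2, 3)
                              if not (s == "Glc" and c == "c1" and r == 1)})
        p = tmp_path / "exp.xlsx"
        write_template(e, p)
        e2 = read_template(p)
        assert e2.n_measurements() == 11
        assert not (e2.data["value"] == 0).any()

    def test_non_numeric_cell_skipped_with_warning(self, tmp_path, caplog):
        e = build_experiment()
        p = tmp_path / "exp.xlsx"
        write_template(e, p)
        from openpyxl import load_workbook
        wb = load_workbook(p)
        wb["data"].cell(row=5, column=4, value="n.d.")
        wb.save(p)
        with caplog.at_level("WARNING"):
            e2 = read_template(p)
        assert e2.n_measurements() == 11
        assert any("non-numeric" in r.message for r in caplog.records)

    def test_duplicate_substance_row_rejected(self, tmp_path):
        e = build_experiment()
        p = tmp_path / "exp.xlsx"
        write_template(e, p)
        from openpyxl import load_workbook
        wb = load_workbook(p)
        ws = wb["data"]
        ws.append(["Glc", "metabolite", "mM", 1.0])
        wb.save(p)
        with pytest.raises(TemplateError, match="duplicate substance"):
            read_template(p)

    def test_roundtrip_property_random_experiments(self, tmp_path):
        rng = np.random.default_rng(7)
        for trial in range(10):
            subs = [Substance(f"s{i}", "metabolite", "mM")
                    for i in range(int(rng.integers(1, 5)))]
            conds = [Condition(f"c{i}") for i in range(int(rng.integers(1, 4)))]
            rec = []
            for s in subs:
                for c in conds:
                    for r in range(1, int(rng.integers(1, 4)) + 1):
                        if rng.random() < 0.8:
                            rec.append((s.name, c.name, float(rng.integers(0, 3)),
                                        "d", r, float(rng.normal())))
            e = Experiment(subs, conds, pd.DataFrame(rec, columns=DATA_COLUMNS))
            p = tmp_path / f"t{trial}.xlsx"
            write_template(e, p)
            assert read_template(p) == e


class TestCsvLong:
    COLMAP = {"substance": "sub", "condition": "cond", "replicate": "rep",
              "value": "val"}

    def test_six_rows_fold_into_tensor(self, tmp_path):
        df = pd.DataFrame({"sub": ["a"] * 3 + ["b"] * 3, "cond": ["c1"] * 6,
                           "rep": [1, 2, 3] * 2, "val": [1.0, 2, 3, 4, 5, 6]})
        p = tmp_path / "d.csv"
        df.to_csv(p, index=False)
        e = read_csv_long(p, self.COLMAP)
        assert e.n_measurements() == 6
        assert set(e.substance_names()) == {"a", "b"}

    def test_missing_declared_column_raises(self, tmp_path):
        p = tmp_path / "d.csv"
        pd.DataFrame({"sub": ["a"], "val": [1.0]}).to_csv(p, index=False)
        with pytest.raises(ConfigurationError, match="cond"):
            read_csv_long(p, self.COLMAP)

    def test_csv_equals_template_import(self, tmp_path):
        e = build_experiment()
        xp = tmp_path / "e.xlsx"
        write_template(e, xp)
        cp = tmp_path / "e.csv"
        e.data.rename(columns={"substance": "sub", "condition": "cond",
                               "replicate": "rep", "value": "val"}
                      ).to_csv(cp, index=False)
        e_csv = read_csv_long(cp, self.COLMAP | {"time": "time"},
                              defaults={"kind": "metabolite", "unit": "mM"})
        e_tpl = read_template(xp)
        assert e_csv == e_tpl


class TestMappingTable:
    def test_rows_and_synonyms(self, tmp_path):
        p = tmp_path / "map.csv"
        p.write_text("Glc,Glucose\nFru,Fructose,D-Fructose\n")
        t = read_mapping_table(p)
        assert len(t) == 2
        assert t.synonyms("Fru") == ["Fructose", "D-Fructose"]

    def test_duplicate_primary_rejected(self, tmp_path):
        p = tmp_path / "map.csv"
        p.write_text("Glc,Glucose\nGlc,Dextrose\n")
        with pytest.raises(ValueError, match="duplicate primary"):
            read_mapping_table(p)

    def test_single_column_rejected(self, tmp_path):
        p = tmp_path / "map.csv"
        p.write_text("Glc\nFru\n")
        with pytest.raises(ValueError, match="no synonym columns"):
            read_mapping_table(p)

    def test_xlsx_table(self, tmp_path):
        from openpyxl import Workbook
        wb = Workbook()
        ws = wb.active
        ws.append(["Glc", "Glucose", None])
        ws.append(["Fru", None, "Fructose"])
        p = tmp_path / "map.xlsx"
        wb.save(p)
        t = read_mapping_table(p)
        assert t.synonyms("Glc") == ["Glucose"]
        assert t.synonyms("Fru") == ["Fructose"]


class TestSummarize:
    def test_closed_form(self):
        e = build_experiment(values={(s, c, r): v for s in ("Glc", "Fru")
                                     for c in ("c1", "c2")
                                     for r, v in ((1, 2.0), (2, 4.0), (3, 6.0))})
        out = summarize(e, "Glc", "c1")
        row = out.loc[0.0]
        assert row["n"] == 3 and row["mean"] == 4.0 and row["sd"] == 2.0
        assert math.isclose(row["sem"], 2.0 / math.sqrt(3))

    def test_single_replicate_sd_absent(self):
        e = build_experiment(n_reps=1)
        row = summarize(e, "Glc", "c1").loc[0.0]
        assert row["n"] == 1 and np.isnan(row["sd"]) and np.isnan(row["sem"])

    def test_all_missing_empty(self):
        subs = [Substance("Glc", "metabolite")]
        e = Experiment(subs, [Condition("c1")],
                       pd.DataFrame(columns=DATA_COLUMNS))
        assert summarize(e, "Glc", "c1").empty

    def test_mean_matches_bruteforce_on_random_data(self):
        rng = np.random.default_rng(11)
        vals = {(s, c, r): float(rng.normal())
                for s in ("Glc", "Fru") for c in ("c1", "c2") for r in (1, 2, 3)}
        e = build_experiment(values=vals)
        for s in ("Glc", "Fru"):
            for c in ("c1", "c2"):
                expect = np.mean([vals[(s, c, r)] for r in (1, 2, 3)])
                assert math.isclose(summarize(e, s, c).loc[0.0, "mean"], expect)


class TestInvariants:
    def test_duplicate_replicate_index_rejected(self):
        subs = [Substance("Glc", "metabolite")]
        df = pd.DataFrame([("Glc", "c1", 0.0, "", 1, 1.0),
                           ("Glc", "c1", 0.0, "", 1, 2.0)], columns=DATA_COLUMNS)
        with pytest.raises(ValueError, match="duplicate replicate"):
            Experiment(subs, [Condition("c1")], df)

    def test_undeclared_substance_rejected(self):
        df = pd.DataFrame([("X", "c1", 0.0, "", 1, 1.0)], columns=DATA_COLUMNS)
        with pytest.raises(ValueError, match="undeclared"):
            Experiment([Substance("Glc", "metabolite")], [Condition("c1")], df)

    def test_substance_name_nonempty(self):
        with pytest.raises(ValueError):
            Substance("", "metabolite")
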