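"""Correlation, two-sample tests, outlier/normality screens, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from omicnet.experiment import Condition, Experiment, Substance, DATA_COLUMNS
from omicnet.graph import AttributedGraph
from omicnet.mapping import map_experiment
from omicnet.stats import (UndefinedCorrelationError, UnsupportedSampleSizeError,
                           ZeroVarianceError, correlate, correlate_n_to_n,
                           correlate_one_to_n, david_quicktest, enrichment,
                           grubbs_critical, grubbs_test, t_test)


def brute_force_pearson(x, y):
    """Product-moment definition from scratch: cov sums and t-based p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    dx, dy = x - x.mean(), y - y.mean()
    r = (dx * dy).sum() / math.sqrt((dx ** 2).sum() * (dy ** 2).sum())
    if abs(r) >= 1:
        return r, 0.0, n
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return r, 2 * sps.t.sf(abs(t), n - 2), n


def profiles_to_experiment(profiles: dict[str, list[float]],
                           kind: str = "metabolite") -> Experiment:
    conds = [Condition(f"c{i}") for i in range(len(next(iter(profiles.values()))))]
    subs = [Substance(name, kind) for name in profiles]
    rec = [(s, c.name, 0.0, "", 1, float(v))
           for s, vals in profiles.items() for c, v in zip(conds, vals)]
    return Experiment(subs, conds, pd.DataFrame(rec, columns=DATA_COLUMNS))


def mapped_graph(profiles: dict[str, list[float]]) -> AttributedGraph:
    g = AttributedGraph()
    for name in profiles:
        g.add_node(node_id=name, label=name, sbgn_class="simple_chemical")
    out, _ = map_experiment(g, profiles_to_experiment(profiles))
    return out


class TestCorrelate:
    def test_perfect_linearity(self):
        r, p, n = correlate([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0) and n == 3

    def test_hand_evaluated_product_moment(self):
        # cov-sum 4, deviation-square-sums 5 and 5 -> r = 4/5
        r, p, n = correlate([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)
        t = 0.8 * math.sqrt(2 / (1 - 0.64))
        assert p == pytest.approx(2 * sps.t.sf(t, 2))

    def test_spearman_monotone_invariance(self):
        x = np.arange(1.0, 11.0)
        r, p, n = correlate(x, x ** 3, method="spearman")
        assert r == pytest.approx(1.0) and p == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=12), rng.normal(size=12)
        r1, p1, _ = correlate(x, y)
        r2, p2, _ = correlate(y, x)
        assert r1 == pytest.approx(r2) and p1 == pytest.approx(p2)
        r3, _, _ = correlate(3.0 * x + 7.0, y)
        assert r3 == pytest.approx(r1)
        rs1, _, _ = correlate(x, y, method="spearman")
        rs2, _, _ = correlate(np.exp(x), y, method="spearman")
        assert rs1 == pytest.approx(rs2)

    def test_spearman_exact_small_n_matches_enumeration(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        r, p, _ = correlate(x, y, method="spearman")
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        hits = total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12:
                hits += 1
        assert p == pytest.approx(hits / total)

    def test_preconditions(self):
        with pytest.raises(UndefinedCorrelationError):
            correlate([1, 2], [3, 4])
        with pytest.raises(UndefinedCorrelationError):
            correlate([1, 1, 1], [1, 2, 3])

    def test_pairwise_complete_deletion(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 5.0, 8.0, np.nan]
        r, p, n = correlate(x, y)
        assert n == 3 and r == pytest.approx(1.0)


class TestOneToN:
    def test_scaled_and_negated_profiles(self):
        base = [1.0, 2.0, 3.0, 4.0, 5.0]
        g = mapped_graph({"T": base,
                          "double": [2 * v for v in base],
                          "anti": [-v for v in base]})
        out = correlate_one_to_n(g, "T")
        assert out.get_attr("node", "double", "correlation.r") == pytest.approx(1.0)
        assert out.get_attr("node", "double", "graphics.fill") == "#0000ff"
        assert out.get_attr("node", "anti", "correlation.r") == pytest.approx(-1.0)
        assert out.get_attr("node", "anti", "graphics.fill") == "#ff0000"

    def test_insufficient_overlap_skipped(self, caplog):
        g = mapped_graph({"T": [1.0, 2.0, 3.0, 4.0],
                          "sparse": [1.0, 2.0, np.nan, np.nan]})
        with caplog.at_level("INFO"):
            out = correlate_one_to_n(g, "T")
        assert out.get_attr("node", "sparse", "correlation.r") is None

    def test_unmapped_target_errors(self):
        g = mapped_graph({"A": [1.0, 2.0, 3.0]})
        with pytest.raises(KeyError):
            correlate_one_to_n(g, "missing")


class TestNToN:
    def test_two_affine_blocks_with_orthogonal_base(self):
        v1 = [-2.0, -1.0, 0.0, 1.0, 2.0]
        v2 = [2.0, -1.0, -2.0, -1.0, 2.0]  # orthogonal to v1 after centering
        profiles = {}
        for i, (a, b) in enumerate([(1, 0), (2, 1), (0.5, -3)]):
            profiles[f"A{i}"] = [a * v + b for v in v1]
            profiles[f"B{i}"] = [a * v + b for v in v2]
        g = mapped_graph(profiles)
        out, res = correlate_n_to_n(g)
        assert len(res.edges) == 6  # 2 blocks x C(3,2), brute-forced over 15 pairs
        for i, j in res.edges:
            assert i[0] == j[0]  # only within-block edges

    def test_unattainable_threshold_gives_no_edges(self):
        g = mapped_graph({"A": [1.0, 2.0, 3.0], "B": [2.0, 4.0, 6.0]})
        _, res = correlate_n_to_n(g, r_min=1.01)
        assert res.edges == []

    def test_matches_allpairs_oracle_on_random_profiles(self):
        rng = np.random.default_rng(42)
        profiles = {f"s{i:02d}": rng.normal(size=15).tolist() for i in range(20)}
        g = mapped_graph(profiles)
        out, res = correlate_n_to_n(g, conf_min=0.95, r_min=0.3)
        oracle_pairs = {}
        oracle_edges = set()
        for a, b in itertools.combinations(sorted(profiles), 2):
            r, p, n = brute_force_pearson(profiles[a], profiles[b])
            oracle_pairs[(a, b)] = (r, p, n)
            if (1 - p) >= 0.95 and abs(r) >= 0.3:
                oracle_edges.add((a, b))
        assert {(i, j) for i, j in res.edges} == oracle_edges
        for (i, j, r, p, n) in res.pairs:
            er, ep, en = oracle_pairs[(i, j)]
            assert r == pytest.approx(er, abs=1e-14)
            assert p == pytest.approx(ep, abs=1e-12)
            assert n == en


class TestTTests:
    def test_identical_samples(self):
        res = t_test([1, 2, 3], [1, 2, 3], "pooled")
        assert res.statistic == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_mannwhitney_exact_enumeration_example(self):
        res = t_test([1, 2], [3, 4], "mannwhitney")
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1 / 3)  # 2 of C(4,2)=6 labelings as extreme

    def test_welch_equals_pooled_for_equal_sizes_and_variances(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a, b = rng.normal(size=8), rng.normal(size=8) + 0.5
            rp = t_test(a, b, "pooled")
            rw = t_test(a, b, "welch")
            assert rp.statistic == pytest.approx(rw.statistic)

    def test_mannwhitney_exact_equals_full_permutation(self):
        rng = np.random.default_rng(9)
        for trial in range(6):
            n_a, n_b = int(rng.integers(2, 5)), int(rng.integers(2, 6))
            a = rng.integers(0, 5, size=n_a).astype(float)  # ties likely
            b = rng.integers(0, 5, size=n_b).astype(float)
            res = t_test(a, b, "mannwhitney")
            pooled = np.concatenate([a, b])
            ranks = sps.rankdata(pooled)
            mu = n_a * n_b / 2
            u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
            us = [ranks[list(idx)].sum() - n_a * (n_a + 1) / 2
                  for idx in itertools.combinations(range(n_a + n_b), n_a)]
            p = np.mean([abs(u - mu) >= abs(u_obs - mu) - 1e-12 for u in us])
            assert res.p == pytest.approx(p)

    def test_pooled_type1_error_calibrated(self):
        rng = np.random.default_rng(2024)
        reps, alpha, n = 5000, 0.05, 8
        a = rng.normal(size=(reps, n))
        b = rng.normal(size=(reps, n))
        res = sps.ttest_ind(a, b, axis=1)
        rate = float(np.mean(res.pvalue <= alpha))
        se = math.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) <= 0.01 + 2 * se

    def test_zero_variance_errors(self):
        with pytest.raises(ZeroVarianceError):
            t_test([1.0, 1.0, 1.0], [2.0, 2.0, 2.0], "pooled")


class TestGrubbs:
    def test_outlier_flagged_against_closed_form(self):
        res = grubbs_test([1.0, 1.0, 1.0, 10.0], alpha=0.05)
        assert res.statistic == pytest.approx(1.5)
        t = sps.t.ppf(1 - 0.05 / 8, 2)
        crit = 3 / math.sqrt(4) * math.sqrt(t * t / (2 + t * t))
        assert res.detail["critical"] == pytest.approx(crit)
        assert crit == pytest.approx(1.48, abs=0.01)
        assert res.detail["outlier_index"] == 3

    def test_symmetric_sample_not_flagged(self):
        res = grubbs_test([-1.0, 0.0, 1.0], alpha=0.05)
        assert res.detail["outlier_index"] is None

    def test_constant_sample_degenerate(self):
        res = grubbs_test([2.0, 2.0, 2.0])
        assert res.detail["degenerate"] and res.detail["outlier_index"] is None


class TestDavidQuicktest:
    def test_rejection_rate_near_alpha_under_null(self):
        rng = np.random.default_rng(7)
        reps, n, alpha = 1000, 10, 0.05
        rejected = sum(david_quicktest(rng.standard_normal(n), alpha) == "rejected"
                       for _ in range(reps))
        rate = rejected / reps
        se = math.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) <= 4 * se

    def test_extreme_spread_rejected(self):
        assert david_quicktest([0.0, 0.0, 10.0], alpha=0.05) == "rejected"

    def test_constant_sample_error(self):
        with pytest.raises(ZeroVarianceError):
            david_quicktest([1.0, 1.0, 1.0])

    def test_unsupported_n(self):
        with pytest.raises(UnsupportedSampleSizeError):
            david_quicktest(list(range(23)), alpha=0.05)


class TestEnrichment:
    def test_hand_summed_tail(self):
        # P(X >= 4) for N=20, K=5, n=5: (C(5,4)C(15,1)+C(5,5))/C(20,5) = 76/15504
        out = enrichment({"a", "b", "c", "d", "e"},
                         set("abcdefghijklmnopqrst"),
                         {"term": {"a", "b", "c", "d", "t"}})
        row = out.iloc[0]
        assert row["k"] == 4 and row["K"] == 5
        assert row["p"] == pytest.approx(76 / 15504)

    def test_zero_overlap_p_is_one(self):
        out = enrichment({"a"}, {"a", "b", "c"}, {"t": {"b"}})
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_query_equals_universe(self):
        uni = {"a", "b", "c", "d"}
        out = enrichment(uni, uni, {"t": {"a", "b"}})
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_matches_fisher_exact_sweep(self):
        rng = np.random.default_rng(1)
        universe = set(range(40))
        for _ in range(25):
            query = set(rng.choice(40, size=rng.integers(1, 20), replace=False).tolist())
            term = set(rng.choice(40, size=rng.integers(1, 25), replace=False).tolist())
            out = enrichment(query, universe, {"t": term}, correction="none")
            k = len(query & term)
            table = [[k, len(term) - k],
                     [len(query) - k, 40 - len(term) - len(query) + k]]
            _, fisher_p = sps.fisher_exact(table, alternative="greater")
            assert out.iloc[0]["p"] == pytest.approx(fisher_p, abs=1e-12)

    def test_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(4)
        universe = set(range(60))
        cats = {f"t{i}": set(rng.choice(60, size=10, replace=False).tolist())
                for i in range(12)}
        query = set(rng.choice(60, size=15, replace=False).tolist())
        out = enrichment(query, universe, cats, correction="bh")
        _, expected, _, _ = multipletests(out["p"].values, method="fdr_bh")
        assert np.allclose(out["p_adj"].values, expected)

    def test_empty_universe_and_bad_query(self):
        with pytest.raises(ValueError):
            enrichment(set(), set(), {})
        with pytest.raises(ValueError):
            enrichment({"z"}, {"a"}, {})
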