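"""Statistical tests, correlation analyses and category enrichment.

Correlation is the workhorse of the network-integration workflow:

* 1:n - one target substance (e.g. the morphological parameter fresh
  weight) is correlated against every other mapped node; the coefficient
  is written onto the nodes and color-coded.
* n:n - all unordered pairs of mapped nodes are correlated; pairs with
  confidence >= ``conf_min`` (i.e. p-value <= 1 - conf_min) and
  |r| >= ``r_min`` induce new correlation edges.  The defaults 0.95 / 0.6
  reproduce the published workflow's thresholds.

Observations are per-condition replicate means; missing cells are handled
by pairwise-complete deletion throughout.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._david_table import DAVID_BOUNDS, SUPPORTED_N
from .graph import AttributedGraph
from .mapping import mapped_nodes, node_profiles

log = logging.getLogger(__name__)


class UndefinedCorrelationError(ValueError):
    """Correlation undefined: too few pairs or zero variance."""


class ZeroVarianceError(ValueError):
    pass


class UnsupportedSampleSizeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# correlation


@dataclass
class CorrelationResult:
    """All pairwise records plus the thresholded edge set they induce."""

    pairs: list[tuple[str, str, float, float, int]]
    method: str
    conf_min: float | None = None
    r_min: float | None = None
    edges: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["i", "j", "r", "p", "n"])


def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def _spearman_exact_p(rx, ry) -> float:
    """Two-sided exact permutation p for Spearman's rho (small n).

    rho is monotone in sum(rx * perm(ry)) for fixed rank vectors, so the
    permutation distribution is enumerated over that inner product.
    """
    n = len(rx)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    perms = np.array(list(itertools.permutations(ry)))
    sx = (rx - rx.mean()) / rx.std()
    sp = (perms - perms.mean(axis=1, keepdims=True)) / perms.std(axis=1, keepdims=True)
    rhos = sp @ sx / n
    return float(np.mean(np.abs(rhos) >= obs - 1e-12))


def correlate(x, y, method: str = "pearson") -> tuple[float, float, int]:
    """Correlation coefficient, two-sided p-value and pairwise-complete n.

    Pearson: product-moment r, p from t = r*sqrt((n-2)/(1-r^2)) against
    Student t with n-2 df.  Spearman: Pearson on mid-ranks; exact
    permutation p for n <= 8, t approximation above.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    x, y = _pairwise_complete(x, y)
    n = len(x)
    if n < 3:
        raise UndefinedCorrelationError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one argument")
    if method == "pearson":
        dx, dy = x - x.mean(), y - y.mean()
        r = float((dx * dy).sum() / math.sqrt((dx ** 2).sum() * (dy ** 2).sum()))
        if abs(r) >= 1.0:
            return max(-1.0, min(1.0, r)), 0.0, n
        t = r * math.sqrt((n - 2) / (1 - r * r))
        return r, float(2 * sps.t.sf(abs(t), n - 2)), n
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 8:
        p = _spearman_exact_p(rx, ry)
    elif abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = 2 * sps.t.sf(abs(t), n - 2)
    return r, float(p), n


def correlate_one_to_n(
    g: AttributedGraph,
    target: str,
    method: str = "pearson",
) -> AttributedGraph:
    """Correlate one substance's profile against every mapped node.

    Each mapped node gains ``correlation.r``, ``correlation.p`` and
    ``correlation.n`` attributes versus the target profile and a fill color
    from the diverging red-white-blue scale.  Nodes with fewer than three
    shared observations are skipped and logged.
    """
    from .viz import color_scale

    out = g.copy()
    profiles = node_profiles(out)
    target_nodes = [n for n in mapped_nodes(out)
                    if target in str(out.get_attr("node", n, "mapping_substances", "")).split("|")]
    if not target_nodes:
        raise KeyError(f"target substance {target!r} is not mapped onto the network")
    tprof = profiles.loc[target_nodes[0]]
    for n in profiles.index:
        try:
            r, p, cnt = correlate(profiles.loc[n], tprof, method=method)
        except UndefinedCorrelationError as exc:
            log.info("1:n correlation: node %s skipped (%s)", n, exc)
            continue
        out.set_attr("node", n, "correlation.r", r)
        out.set_attr("node", n, "correlation.p", p)
        out.set_attr("node", n, "correlation.n", cnt)
        out.set_attr("node", n, "graphics.fill", color_scale(r))
    out.graph_attrs["correlation_target"] = target
    return out


def correlate_n_to_n(
    g: AttributedGraph,
    method: str = "pearson",
    conf_min: float = 0.95,
    r_min: float = 0.6,
) -> tuple[AttributedGraph, CorrelationResult]:
    """All-pairs correlation over mapped nodes; threshold into edges.

    An edge is added iff confidence (1 - p-value) >= ``conf_min`` and
    |r| >= ``r_min``; it is colored by the sign and magnitude of r
    (negative red, positive blue).
    """
    from .viz import color_scale

    out = g.copy()
    profiles = node_profiles(out)
    if len(profiles) < 2:
        raise ValueError("n:n correlation needs at least 2 mapped nodes")
    pairs = []
    edges = []
    index = sorted(profiles.index)
    for i, j in itertools.combinations(index, 2):
        try:
            r, p, n = correlate(profiles.loc[i], profiles.loc[j], method=method)
        except UndefinedCorrelationError:
            continue
        pairs.append((i, j, r, p, n))
        if (1.0 - p) >= conf_min and abs(r) >= r_min:
            edge = out.add_edge(i, j, interaction="correlation")
            out.set_attr("edge", edge, "correlation.r", r)
            out.set_attr("edge", edge, "correlation.p", p)
            out.set_attr("edge", edge, "correlation.n", n)
            out.set_attr("edge", edge, "color", color_scale(r))
            edges.append((i, j))
    return out, CorrelationResult(pairs, method, conf_min, r_min, edges)


# ---------------------------------------------------------------------------
# two-sample tests


@dataclass
class TestResult:
    statistic: float
    p: float | None
    alpha: float
    method: str
    df: float | None = None
    significant: bool | None = None
    detail: dict = field(default_factory=dict)


def _mannwhitney_u(ranks_a_sum: float, n_a: int) -> float:
    return ranks_a_sum - n_a * (n_a + 1) / 2.0


def _mannwhitney_exact(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumeration of all group labelings.

    Mid-ranks are used, so ties are handled exactly; the two-sided p is the
    probability of a U at least as far from its null mean n_a*n_b/2 as the
    observed one.
    """
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a, n = len(a), len(pooled)
    mu = n_a * (n - n_a) / 2.0
    u_obs = _mannwhitney_u(ranks[:n_a].sum(), n_a)
    dist = np.array([_mannwhitney_u(ranks[list(idx)].sum(), n_a)
                     for idx in itertools.combinations(range(n), n_a)])
    return float(u_obs), float(np.mean(np.abs(dist - mu) >= abs(u_obs - mu) - 1e-12))


def t_test(a, b, variant: str = "pooled", alpha: float = 0.05) -> TestResult:
    """Unpaired two-sample location test.

    ``pooled``: Student t with pooled variance; ``welch``:
    Welch-Satterthwaite; ``mannwhitney``: rank-based U test, exact by
    enumeration when n_a + n_b <= 12, normal approximation with tie
    correction otherwise.  All p-values are two-sided.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    n_a, n_b = len(a), len(b)
    if variant in ("pooled", "welch"):
        if n_a < 2 or n_b < 2:
            raise ValueError("t-test needs >= 2 values per group")
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if np.mean(a) == np.mean(b):
                return TestResult(0.0, 1.0, alpha, variant,
                                  df=n_a + n_b - 2, significant=False)
            raise ZeroVarianceError("both samples constant with different means")
        res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
        df = float(res.df)
        return TestResult(float(res.statistic), float(res.pvalue), alpha, variant,
                          df=df, significant=bool(res.pvalue <= alpha))
    if variant == "mannwhitney":
        if n_a < 1 or n_b < 1 or n_a + n_b < 4:
            raise ValueError("Mann-Whitney needs n_a, n_b >= 1 and n_a + n_b >= 4")
        if n_a + n_b <= 12:
            u, p = _mannwhitney_exact(a, b)
            method = "mannwhitney-exact"
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            u, p = float(res.statistic), float(res.pvalue)
            method = "mannwhitney-normal"
        return TestResult(u, p, alpha, method, significant=bool(p <= alpha))
    raise ValueError(f"unknown t-test variant {variant!r}")


# ---------------------------------------------------------------------------
# outlier and normality screening


def grubbs_critical(n: int, alpha: float) -> float:
    """Closed-form Grubbs critical value via the Student t quantile."""
    t = sps.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_test(x, alpha: float = 0.05) -> TestResult:
    """Single-outlier screen: G = max|x_i - mean| / sd vs. G_crit(alpha, n).

    Flags the most extreme point when G exceeds the critical value; a
    constant sample is degenerate (sd = 0) and flags nothing.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        return TestResult(0.0, None, alpha, "grubbs", significant=False,
                          detail={"outlier_index": None, "degenerate": True})
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx] / sd)
    crit = grubbs_critical(n, alpha)
    flagged = g > crit
    return TestResult(g, None, alpha, "grubbs", significant=flagged,
                      detail={"outlier_index": idx if flagged else None,
                              "critical": crit, "degenerate": False})


def david_quicktest(x, alpha: float = 0.05) -> str:
    """Range/sd normality quick test.

    q = (max - min)/sd is compared against two-sided critical bounds for
    (n, alpha); returns ``"consistent-with-normal"`` or ``"rejected"``.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if alpha not in (0.05, 0.01):
        raise ValueError("alpha must be 0.05 or 0.01 (tabulated levels)")
    if (n, alpha) not in DAVID_BOUNDS:
        raise UnsupportedSampleSizeError(
            f"n={n} not tabulated (supported: {SUPPORTED_N})")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("constant sample: range/sd undefined")
    q = float(np.ptp(x) / sd)
    lo, hi = DAVID_BOUNDS[(n, alpha)]
    return "consistent-with-normal" if lo <= q <= hi else "rejected"


# ---------------------------------------------------------------------------
# category enrichment


def enrichment(
    query: set,
    universe: set,
    categories: dict[str, set],
    correction: str = "bh",
) -> pd.DataFrame:
    """Over-representation of category terms in a query set.

    For each term: k = |query & term|, K = |term & universe|, n = |query|,
    N = |universe|; p is the hypergeometric upper tail P(X >= k)
    (equivalently one-sided Fisher's exact).  Benjamini-Hochberg adjustment
    optional.
    """
    query, universe = set(query), set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError(f"query not contained in universe: "
                         f"{sorted(query - universe)[:5]}...")
    N, n = len(universe), len(query)
    rows = []
    for term in sorted(categories):
        members = set(categories[term]) & universe
        K = len(members)
        k = len(members & query)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if correction == "bh":
        m = len(out)
        order = np.argsort(out["p"].values, kind="stable")
        adj = np.empty(m)
        prev = 1.0
        for rank_from_end, i in enumerate(order[::-1]):
            rank = m - rank_from_end
            prev = min(prev, out["p"].values[i] * m / rank)
            adj[i] = prev
        out["p_adj"] = adj
    elif correction == "none":
        out["p_adj"] = out["p"]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return out
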