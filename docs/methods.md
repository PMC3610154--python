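# Methods

This note records the models, conventions, numerical choices and known
limitations behind each module. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Attributed graph model

Networks are directed multigraphs. Every element (graph, node, edge)
carries a flat dictionary of scalar attributes keyed by dotted
hierarchical paths (`graphics.fill`, `centrality.betweenness`,
`mapping.<substance>.<condition>.<time>.<replicate>`). Restricting values
to scalars (str/int/float/bool) is what makes lossless file round-trips
possible; list-valued concepts (synonym lists) are stored as
`|`-delimited strings with dedicated accessors. Coordinates follow the
screen convention — origin top-left, y grows downward, node anchor at the
center — matching typical graph-editor output.

Because substance and condition names may themselves contain dots, path
components are percent-escaped (`%` → `%25`, `.` → `%2E`) before joining,
so paths always split unambiguously.

Node identity is an opaque internal id; labels are ordinary attributes and
may legitimately repeat (pre-merge pathway collections). Operations that
key on labels (`merge_networks`) say so explicitly.

### File formats

GML and GraphML are full-fidelity: write∘read is the identity on any
attributed graph (property-tested on randomized graphs with adversarial
keys and values). GraphML carries arbitrary keys and typed values
natively. The GML dialect accepted by the underlying writer restricts
keys to identifiers and has no boolean type, so a reversible escaping
layer is applied: non-identifier key components are written as
`vK<hex-escaped>`, booleans as `vB:0/1` marker strings, and the internal
node/edge ids as `vKnid`/`vKeid` entries. Foreign GML files (no markers)
read naturally; the `label` block is then authoritative.

SIF keeps only topology and the interaction type (one line per edge,
single-name lines for isolated nodes). SBML (Level 2/3 core) is read-only
and expanded bipartitely: species → simple-chemical nodes, reactions →
process nodes, stoichiometric coefficients → edge weights, reversibility
and boundary conditions → node attributes; kinetics are ignored.

### Structural editing

`merge_networks` forms the disjoint union, then fuses nodes sharing a key
value (optionally restricted to SBGN classes); the fused node inherits the
union of synonyms and all incident edges. Fusing nodes of different SBGN
classes is an error listing the offenders. `split_node` replaces a node of
degree d ≥ 2 by d clones, one per incident edge (a self-loop counts once
and its clone keeps the loop); degree < 2 is a no-op. Edge multiplicity is
allowed throughout so split/merge cycles are lossless up to multiplicity.

## Experiment model and template dialect

Measurements are held in long form (substance, condition, time, time
unit, replicate, value); missing cells are absent rows, never imputed
zeros, and all downstream statistics use pairwise-complete observations —
ecotype panels are ragged in practice.

The XLSX template dialect is self-defined (no claim of file-level
compatibility with any other tool): sheet `meta` holds key/value header
fields, optional sheet `conditions` holds per-condition metadata, and
sheet `data` has four header rows (condition, time value, time unit,
replicate index) over the measurement columns, with substance name / kind
/ unit in columns A–C and the matrix from row 5. XLSX numeric cells carry
16 significant digits, so the write/read identity holds to that precision
(Experiment equality compares values at relative 1e−14).

Long CSV import takes a role→column map (`substance` and `value`
required) plus constant defaults for roles without a column; replicate
indices are synthesized per (substance, condition, time) when absent.

## Data mapping

Matching is exact after trimming and case-folding (a strict mode exists);
fuzzy or database-backed identifier resolution is out of scope. The class
rule (kind → admissible SBGN class) defaults to metabolite→simple
chemical, enzyme/gene→macromolecule, morphological/other→unspecified. A
substance matching several admissible nodes — split cofactor nodes are
the legitimate case — is mapped to **all** of them and reported as
ambiguous. Mapping never changes topology except for creating isolated
nodes for unmatched substances when requested. The condition order is
recorded as a graph attribute at mapping time so profiles stay aligned
across nodes. Substance kind/unit/synonyms ride along under
`mappingmeta.*`, which is what makes export → re-import → re-map the
identity.

## Statistics

* **Pearson** r is computed from the product-moment definition; p is
  two-sided from t = r√((n−2)/(1−r²)) with n−2 df. |r| ≥ 1 short-circuits
  to p = 0. Fewer than 3 complete pairs or zero variance is an error, not
  a NaN.
* **Spearman** uses mid-ranks. The permutation p is exact (full
  enumeration, vectorized) for n ≤ 8 — 8! = 40320 permutations is the
  practical enumeration limit — and the t approximation above that.
* **n:n thresholding**: an edge requires confidence 1−p ≥ `conf_min` and
  |r| ≥ `r_min`; defaults 0.95 and 0.6. The confidence phrasing means a
  p-value ≤ 0.05 — selecting for *high* p-values would pick the
  non-significant pairs. No multiple-testing correction is applied by
  default (the thresholds are raw by design); BH is available in
  `enrichment` and can be applied to the pair table externally.
* **Mann-Whitney** is exact by enumeration of all C(n_a+n_b, n_a)
  labelings (mid-ranks, so ties are handled exactly) for n_a+n_b ≤ 12,
  and the normal approximation with tie correction above. The two-sided p
  is the null probability of a U at least as far from n_a·n_b/2 as
  observed.
* **Grubbs**: G = max|x_i − x̄|/s against the closed-form critical value
  ((n−1)/√n)·√(t²/(n−2+t²)), t the upper α/(2n) Student quantile with
  n−2 df. Constant samples are degenerate and flag nothing.
* **Range/sd normality quick test**: q = (max−min)/s against two-sided
  critical bounds per (n, α), α ∈ {0.05, 0.01}, n ∈ {3..20, 25, ..., 100}.
  The bounds in `_david_table.py` were computed once by Monte-Carlo
  simulation of the null distribution (10⁶ standard-normal samples per n,
  fixed seed) and are frozen in source; the suite verifies the resulting
  rejection rate is calibrated to α under the null.
* **Enrichment**: hypergeometric upper tail P(X ≥ k) with N = |universe|,
  K = |term ∩ universe|, n = |query| — identical to one-sided Fisher's
  exact on the 2×2 table (asserted against an independent implementation);
  BH adjustment optional.

## SOM clustering

Grid 1×k by default (the target is a cluster count, not a 2-D map; 2-D
grids are available via `grid=`). Prototypes are initialized from seeded
draws of the data rows; per epoch the rows are presented in a seeded
shuffle and every unit moves toward the sample weighted by a Gaussian
neighborhood in grid space. Rate and radius decay exponentially to 1% of
their initial values (defaults: rate 0.5, radius max(grid)/2, 100
epochs). Rows are z-scored per profile by default since metabolite,
enzyme and morphological units are incomparable; missing cells are
mean-imputed per row at training time only. Assignment is the nearest
prototype with ties to the lowest unit index (distances rounded at 1e−12
so exact geometric ties are stable). Training is bit-reproducible per
seed. The schedule constants are exposed; none are claimed optimal.

## Topology

Degrees are raw counts. Closeness is the harmonic variant (sum of
reciprocal distances), which is well defined on disconnected graphs;
eccentricity is per connected component; betweenness is Brandes'
algorithm with unnormalized pair counting on the undirected simple view;
eigenvector centrality is power iteration (tol 1e−10, ≤ 10⁴ iterations)
on the undirected view; Katz uses α = 0.05 on the directed view. Cycle
enumeration is Johnson's elementary-circuit algorithm with a configurable
cap and truncation flag (undirected: cycle basis). Motif search is
injective subgraph matching, non-induced by default (every pattern arc
must exist; extra host arcs allowed), induced optionally; matches are
deduplicated by pattern automorphism; pattern nodes with a specific SBGN
class only match that class. Patterns are limited to 8 nodes.

## Petri nets

Translation requires a bipartite metabolite/process graph with positive
integral edge weights; reversible processes expand into two opposing
transitions; the default marking is all zeros so unbounded runs never
start by accident. Invariants are computed by Farkas / Fourier–Motzkin
elimination on [C | I] in exact Python-integer arithmetic, then
gcd-normalized and reduced to minimal support (rows whose support
strictly contains another's are dropped). Reachability is BFS over the
firing rule with a state cap (default 10⁵) and truncation flag. The
`maximal` simulation policy fires each enabled transition once per step
in index order, skipping those disabled mid-step. PNML interchange covers
the basic place/transition subset. Continuous and hybrid nets, coverability
and model checking are out of scope.

## Constraint-based analysis

`from_graph` builds S from edge weights (consumed negative, produced
positive). Metabolites flagged `boundary` are dropped from the balance
rows, so processes touching only boundary metabolites act as the model's
exchange reactions — the explicit alternative of synthesizing separate
exchange columns is equivalent up to reaction naming. Irreversible
reactions get lb = 0, reversible lb = −default_bound; node `lb`/`ub`
attributes override. LPs are solved with HiGHS at 1e−9 feasibility
tolerance. FBA returns one solver-chosen vertex — LP degeneracy makes the
optimal vertex non-unique, so uniqueness statements must go through FVA
(2 LPs per reaction with c^T v ≥ f·z* added; f defaults to 1.0).
Robustness clamps a reaction at `n_steps` (default 20) evenly spaced
values across its f = 0 feasible range and records the objective; for an
LP the curve is concave, which the suite checks by second differences.

## Visualization

Glyphs approximate SBGN: circles for simple chemicals, rounded rectangles
for macromolecules, small squares for processes; no SBGN-ML compliance is
claimed. Charts (bar, pie, line, heatmap) draw per-condition replicate
means inside the glyph in declared condition order; each node's chart is
one SVG group (`chart-<node>`), which makes figures inspectable by
markup. The correlation color scale maps [−1, 1] linearly to red — white —
blue with clamping; it is odd-symmetric (the color of −r is the red/blue
mirror of the color of r). Flux edge thickness is linear:
t_min + (t_max−t_min)·|v|/max|v|. Layouts: seeded Fruchterman–Reingold
(deterministic per seed, with collision jitter), circle, grid, BFS-layer
tree (cyclic input is an error), and pathway circles (each pathway on its
own circle, circles arranged on an outer ring). Expression-matrix layout
and edge routing are non-goals. HTML export writes a client-side image
map with one rectangular region per node and hyperlinks from `url`
attributes.

## Synthetic study data

The generator emulates the shape of a published *Arabidopsis thaliana*
ecotype panel: 64 metabolites, 37 enzyme activities and one morphological
target ("FW") across 50 ecotype conditions, 3 replicates. Substance
profiles follow per-condition latent pathway factors,
z_s = ρ·f_block + √(1−ρ²)·ε_s, with ε empirically orthogonalized against
the factor so the planted factor correlation is exact in-sample; the
default plants 4 blocks of 12 metabolites at ρ = 0.9. The morphological
target is regression-constructed from named substance profiles so its
planted marginal correlations are exact; coupled substances outside
blocks are first orthogonalized among themselves (they are independent by
design, and this keeps the implied correlation matrix positive
semidefinite for every seed — the generator rejects genuinely infeasible
coupling vectors). Replicates add i.i.d. Gaussian noise (default sd 0.2 of
the substance scale); a missingness rate is exposed but defaults to 0
because the real panel's missing-value pattern is unknown. Ground truth
(block membership, codes, planted edges) travels in a sidecar dictionary,
never inside the Experiment.

What the generator does **not** emulate: heteroscedastic measurement
error, batch effects, non-Gaussian metabolite distributions, structured
missingness, or real pathway stoichiometry. Passing tests therefore
demonstrate correctness of the algorithms under the planted model, not
biological validity on real panels.

The default problem sizes (50-condition panels, 4-cluster SOM runs of 200
rows, 5000-replicate test calibration, 100 round-trip graphs) were chosen
so the entire suite and the acceptance script each complete in well under
a minute of CPU while keeping Monte-Carlo standard errors far below the
asserted margins.

## Known limitations

* GML files written by other tools round-trip through reading, but
  writing re-encodes keys; bit-identical re-emission of foreign files is
  not attempted.
* Spearman's exact p stops at n = 8; between 9 and ~15 the t
  approximation is used where some references tabulate exact values.
* The Farkas invariant computation is exponential in the worst case; it
  is intended for the small-to-medium nets of curated pathway models.
* `fba` on unbounded models reports status and returns no vertex.
* Chart geometry inside glyphs is this package's own design; figures are
  not pixel-compatible with any desktop tool.
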