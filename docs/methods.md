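# Methods

## Model and assumptions

The package infers an undirected co-expression network over genes from a
genes × samples expression matrix. The underlying assumption is the
standard guilt-by-association one: genes whose expression profiles
co-vary across samples are likely functionally related. No directionality,
causality or conditional-independence structure is claimed — the method
scores marginal pairwise dependency only.

Two further assumptions shape the optimization step: (a) of the many
edges a correlation screen produces, the biologically meaningful
backbone is well approximated by the maximum-weight spanning forest
(strongest path between any two genes); (b) high-degree nodes of that
backbone (hubs) are candidate regulators whose pruned edges deserve a
second look. Both are heuristics about network structure, not
statistical guarantees.

## Dependency measures

Each measure maps a pair of profiles to [0, 1], 0 = no dependency,
1 = total dependency.

- **Spearman**: |ρ| of the average-ranked profiles (scipy). Absolute
  value, because strong negative co-expression is still co-expression;
  folding is the only mapping consistent with the [0, 1] scale.
- **Kendall**: |τ_b|, the tie-corrected variant (scipy). Expression
  data, especially discretized or low-count data, contain ties; τ_b
  keeps ±1 reachable under ties.
- **NMI**: each profile is discretized independently into B
  equal-frequency bins; I(X;Y) and the marginal entropies come from the
  joint contingency table, and NMI = I / √(H(X)H(Y)). The geometric-mean
  normalizer is symmetric and bounds the score by 1.

**Bin count.** `bins="auto"` uses B = ⌈n^(1/3)⌉ (minimum 2). The
finite-sample bias of the plug-in MI estimate is ≈ (B−1)²/(2n) nats;
with the cube-root rule this stays well below the marginal entropies, so
independent profiles score near 0 (measured ≈ 0.02 at n = 1000) while
NMI(x, x) = 1 exactly. A square-root rule (B = ⌈√n⌉) inflates the
independence baseline to ≈ 0.16 at n = 1000 — large enough to distort
voting at permissive thresholds — which is why the cube-root rule is the
default. B is user-configurable.

**Degenerate inputs.** Constant profiles score 0 on all three measures
(a constant gene carries no co-expression signal; avoids NaN
propagation). Pairs are scored on pairwise-complete samples; below 3
complete samples the pair scores 0 and a warning is logged. Profiles
must have ≥ 3 samples (rank correlations degenerate below that).

**Significance.** Measure i calls a pair significant when vᵢ ≥ Thᵢ
(inclusive, so Th = 1.0 still admits perfect dependencies); a strict
variant is available via `inclusive=False`.

## Ensemble network

An edge exists iff ≥ 2 of 3 measures call the pair significant. Its
weight w_en is the arithmetic mean of **all three** scores, including a
score below its own threshold — so weights are independent of the
thresholds, and raising a threshold can only remove edges (monotonicity,
property-tested). Genes with no confirmed edge are dropped from the node
set by default (`keep_isolated=True` retains the full universe), so
reported node counts mean connected genes.

## Pruning and hub re-insertion

`maximum_spanning_forest` is Kruskal's algorithm on edges sorted by
(descending weight, then lexicographic canonical pair). The tie-break
makes output unique and byte-reproducible; without it, equal-weight
edges would make the forest depend on iteration order. Disconnected
inputs are handled per component (m−1 edges per m-node component), the
only generalization preserving "acyclic + spans all nodes".

Hubs are nodes whose degree **strictly** exceeds the mean degree
2m/n of the pruned network — the comparison is made on the pruned
network, where degrees reflect backbone connectivity rather than raw
correlation counts. A removed ensemble edge returns to the network when
it touches a hub and its w_en **strictly** exceeds Thβ (an inclusive
variant exists for sensitivity analysis). Weights are carried over from
the ensemble step, never recomputed. Hub detection happens once, before
re-insertion; the process is not iterated.

## Topology diagnostics

All path statistics use hop counts; edge weights are ignored (the
diagnostics describe wiring, and diameters are meant to be small
integers). For disconnected networks — the usual case here, a forest
plus hub edges — CPL and diameter are computed over finite pairs only.
Density is 2m/(n(n−1)); clustering is the mean local coefficient with
degree-<2 nodes contributing 0.

γ is estimated by least squares of log count(k) on log k over degrees
k ≥ 1 with nonzero count — the convention of classic network-analysis
tools, chosen for comparability; a continuous-approximation
maximum-likelihood estimator (`method="mle"`) is provided for robustness
checks. Fewer than two usable degrees ⇒ γ is reported as absent ("-" in
the summary row). Degree-0 nodes are excluded from the fit (log
undefined) but counted in density and clustering. Note that on networks
of a few dozen nodes the least-squares γ is a descriptive statistic, not
a reliable exponent estimate.

## Evaluation

Edges are canonical unordered string pairs; TP/FP/FN are plain set
operations against the gold standard, with precision = TP/(TP+FP) and
recall = TP/(TP+FN). By default FN counts the **full** gold standard —
against a database-scale reference this yields the characteristically
tiny recall values and is the honest default; `restrict_gold` limits
gold edges to the network's gene universe. Identifier matching is exact
string comparison, optionally after uppercasing; alias/ortholog
resolution is dataset curation, out of scope.

An empty inferred network has undefined precision, reported as absent
rather than 0.

## Synthetic data generator

`generate_fixture` plants co-expressed modules in independent Gaussian
noise: module gene i is √ρ·L + √(1−ρ)·εᵢ with a shared latent profile L,
giving expected within-module pairwise correlation ρ; background genes
are independent N(0, noise_sd²). Defaults used throughout the tests and
the acceptance benchmark: 200 samples, module correlation 0.90–0.95
(strong co-expression, the regime the 0.7–0.9 threshold grid targets),
two 6-gene modules among 50 background genes.

The generator reproduces the *covariance structure* of co-expressed
groups, not the marginals of real expression data: no mean–variance
trend, skew, counts, dropout, batch effects, or overlapping modules.
Passing tests therefore demonstrate that the pipeline recovers planted
dependency structure and obeys its structural invariants — not that any
particular precision would be achieved on a real dataset against a
curated gold standard.

## Numerical and design notes

- Scores are clipped to [0, 1] against floating-point excursions
  (e.g. |ρ| = 1 + 1e−16).
- Edge lists are written in lexicographic pair order with 6-decimal
  weights; identical runs are byte-identical.
- The single-measure baselines (`--method spearman|kendall|nmi`)
  threshold one measure's raw score and use it directly as the edge
  weight — no averaging — so they are genuine one-measure comparators.
- `--method ensemble-only` is exactly step 1; its edge list matches the
  full pipeline's `ensemble.tsv` byte-for-byte.
- Problem sizes in the tests and the acceptance benchmark (≤ 62 genes,
  ≤ 200 samples, 200 random graphs of ≤ 7 nodes for the spanning-forest
  oracle) were chosen so that exhaustive oracles remain feasible and the
  suite runs in minutes; the pipeline itself is O(G² · n log n) in genes
  and samples and handles thousands of genes.

## Known limitations

- All-pairs scoring is quadratic in the gene count and single-threaded;
  very large matrices (> ~5000 genes) take correspondingly long.
- The NMI estimator is a plug-in histogram estimator; at small n its
  residual bias is nonzero (≈ 0.02 at n = 1000 under independence).
- The spanning-forest backbone is a global heuristic: an edge can be
  pruned even when it is the only evidence linking two modules, and only
  hub-incident edges are eligible for recovery.
- γ from least squares on a small-network histogram is noisy and can be
  far from the asymptotic exponent of a generative model.
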