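# Methods

## Statistical model of the screen

The discovery cohort is two groups of log2 expression profiles (features ×
samples) assumed approximately Gaussian on the log2 scale within groups.
With ~6 samples per arm, per-feature variance estimates are too unstable
for an ordinary t-test, so the screen uses a random-variance-model
moderated t-test: precisions 1/σ² are modeled as Gamma(a, b) across
features, under which the pooled sample variance satisfies
s²·a·b ~ F(d, 2a) with d = n₁+n₂−2 residual degrees of freedom. The prior
(a, b) is fitted once per matrix by maximizing the F marginal likelihood
over (log a, log b) (Nelder–Mead from the fixed start a = 1,
b = 1/mean(s²), tolerances 1e-10), making the fit deterministic and
invariant to feature order. Each feature then uses the moderated variance
σ̃² = (d·s² + 2/b)/(d + 2a) and the statistic

    t = (x̄₁ − x̄₂) / (σ̃ · √(1/n₁ + 1/n₂)),   t ~ t(d + 2a) under H₀.

As (a, 1/b) → 0 this reduces exactly to the pooled two-sample t-test (a
test asserts agreement to 1e-9); under the variance model it is type-I
calibrated, which the suite checks empirically on a 2000-feature null.

Degenerate inputs: exactly constant observed variances leave the F family
unidentified (the likelihood climbs toward a → ∞) and raise a fit error.
Merely homogeneous data (equal true variances, chi-square scatter in s²)
instead hit a cap a ≤ 1e6 with a warning; the test then degrades
gracefully to a pooled z-test with the common variance, which is the
correct limit, so whole-pipeline runs on homoscedastic cohorts do not
abort.

Significance is gated on |log2FC| > 0.5 and p < 0.05, both strict.
Benjamini–Hochberg q-values are always computed and reported; an optional
configuration switch additionally gates on q. Hierarchical clustering of
the significant features (default 1 − Pearson distance, average linkage,
via SciPy's agglomerative implementation with its deterministic
tie-handling) is provided for heat-map-style inspection and Newick export.

## Network construction

**Co-expression.** Candidate miRNA→target pairs are the set intersection
of two prediction tables (pairs must be reported by both programs). An
edge requires: both endpoints significant in the screen; Pearson r < 0
across all samples pooled (the network describes the discovery cohort as
a whole, not a per-group relationship); correlation p < 0.05; and
opposite fold-change directions. Each clause can be toggled. The key
miRNA is the maximum-degree node (ties: larger |log2FC|, then id).

**Signal transduction.** Interactions whose combined confidence score is
*strictly greater* than the median of **all** scores in the input table
(median taken before restricting to differentially expressed genes — the
alternative ordering is configurable) and whose endpoints are both DE form
a simple undirected graph. Topological features per node:

- degree;
- relative betweenness C′B(v) = [2/(n²−3n+2)]·Σ_{s≠v≠t} σst(v)/σst,
  computed by Brandes' BFS accumulation (networkx); the prefactor equals
  the standard undirected normalization 2/((n−1)(n−2)), so C′B ∈ [0, 1]
  on connected graphs; cross-component pairs contribute zero;
- closeness C(i) = 1/Σ_y d(y, i) with the farness summed over the node's
  connected component only; an isolated node gets 0. (This differs from
  networkx's rescaled closeness, hence the thin in-package definition.)

Hub genes must exceed the median of all three features *simultaneously
and strictly* — a deliberately conservative reading that makes regular
graphs hub-free. Edge betweenness is reported unnormalized (summed
shortest-path fractions over unordered pairs); only the ranking matters
for key-interaction selection, and ties at the top are all kept.

**Markov clustering.** Modules come from flow simulation on the
column-stochastic adjacency matrix with unit self-loops: repeated
expansion (matrix power e) and inflation (elementwise power r with column
renormalization), pruning entries below `prune_min`, until the matrix
changes by less than `tol` or `max_iter` is reached (non-convergence is
reported, not raised). Defaults: e = 2, r = 2, prune 1e-5, tol 1e-8,
100 iterations. Clusters are read from the limit matrix: rows with
positive diagonal are attractors, their supports span clusters,
overlapping attractor systems merge, and a node claimed by several
clusters goes to the one holding more of its column mass (ties to the
smaller module id), so the partition is always a deterministic exact
cover. No reference MCL implementation ships in the dependency set; the
fixed-point partitions asserted in tests (two disjoint triangles → two
3-modules; twin 3-cliques bridged by one edge, inflation 2 → {3, 3})
follow analytically from component structure and symmetry.

Module enrichment is the one-sided hypergeometric tail P(X ≥ k) for the
overlap between a module and a gene set within the network's gene
universe, BH-corrected across all (module, set) pairs.

## Panel assembly and classification

The top-k edges by betweenness (default k = 2, cutoff ties included)
nominate anchor genes in rank order. Each anchor gene contributes its
incident miRNA with the smallest screen p-value (ties: larger |log2FC|,
then id); duplicates keep their first anchor. Panel size is therefore
emergent. Anchors without an upstream miRNA are recorded and skipped.

The classifier is a soft-margin RBF SVM (responder = +1) trained by the
libsvm dual solver (scikit-learn). Defaults C = 1 and γ =
1/(n_features · var(X)) — the standard heuristic for this toolchain; both
are configurable. Feature scaling (default z-score with population SD)
is fitted on training samples only, inside every cross-validation fold,
to avoid leakage. A decision value of exactly 0 maps to +1. Evaluation:

- repeated stratified k-fold CV (default 5×5; stratification guarantees
  both classes in every training split at n = 12); per repeat, confusion
  counts and decision values are pooled over folds; headline metrics
  average the repeats;
- sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/N;
  an undefined ratio is NaN with a warning, never silently 0;
- AUC = Mann–Whitney probability (ties ½), verified against brute-force
  pair counting; ROC points by threshold sweep;
- AUC comparisons by the two-sided DeLong test for correlated curves
  (identical score vectors → p = 1; zero-variance differences with a
  non-zero gap are reported as not computable);
- clinical covariates compared as univariate scores with orientation
  flipped so AUC ≥ 0.5 (the flip is reported);
- qPCR validation via the comparative-CT method, fold = 2^−ΔΔCt after
  reference-gene normalization.

## What the synthetic generator emulates — and what it does not

`SyntheticSpec` defaults encode the reference study conditions: 6
responders vs 6 non-responders, 60 miRNAs, 150 genes, 4 planted miRNAs
with |Δ| = 1.5 log2 units (signs alternating up/down), coupling β = 1,
noise σ_e = 0.3 log2 units, 5 targets per planted miRNA, decoy fraction
0.5, interaction modules of 5 and 4 genes plus 40 background edges.
Background features are baseline + N(0, σ_e) in both groups; planted
miRNAs add ±Δ to responders; each true target is
baseline − β·(centered miRNA) + N(0, σ_e), giving r ≈
−√(V/(V+σ_e²)) ≈ −0.94 at the defaults and the opposite fold change.
Baselines are drawn once from a fixed RNG keyed to feature identity, so
independently seeded cohorts share each feature's intensity scale the way
repeated profiling runs of real specimens do; all other randomness is a
pure function of (spec, seed) via NumPy's PCG64.

Decoy prediction pairs appear in exactly one of the two emitted tables
(alternating), so the source intersection removes precisely the decoys.
The interaction table carries two cliques over designated target genes
(round-robin across planted miRNAs, so every planted miRNA owns at least
one module gene and the recovered panel can equal the planted set) joined
by one bridge; community and bridge scores are drawn in (0.60, 0.95),
filler edges between background genes in (0.10, 0.40). The table always
contains at least as many low-score filler edges as high-score edges —
otherwise the global median would fall inside the high band and the
strict >-median filter could not retain the planted structure; with that
guarantee the filtered graph is exactly cliques + bridge, and the bridge
is the unique maximum of edge betweenness.

Not emulated: probe-level artifacts, batch effects, intensity-dependent
variance, correlated background genes, hub-degree heterogeneity of real
interactomes, and qPCR amplification noise. Passing the recovery tests
therefore demonstrates that the pipeline's logic is sound under its own
assumptions — not that real cohorts of this size will yield panels of
this quality.

Under the default conditions each planted miRNA has a within-group effect
size Δ/σ_e = 5, so single markers, like the panel, usually cross-validate
at AUC 1.0. The panel-vs-single-marker comparison is therefore asserted
as non-strict dominance (the panel is never outperformed by any single
marker), the attainable analogue of the combined model's advantage.

## Problem sizes and runtime choices

The test suite and the acceptance script size their simulations for a
single CPU: 100 random graphs with n ≤ 8 for the centrality oracles,
2000-feature nulls for calibration, 200 small cohorts for the
permutation null, 50 (tests) or 25 (acceptance script) seeds for the
planted-recovery rate. These sizes give binomial standard errors
comfortably inside the asserted bands.

## Known limitations

- The RVM prior fit assumes a common residual df across features
  (complete two-group design, no missing values).
- The co-expression correlation pools both groups, so a pair driven by a
  strong group effect alone can pass the r < 0 clause; the
  opposite-direction clause is what keeps such edges biologically
  interpretable.
- MCL module reading assigns every node to exactly one module; genuinely
  overlapping cluster structure is collapsed by the mass rule.
- The pipeline's resumability is inspection-level (manifest of completed
  stages and digests), not automatic checkpoint restart.
- Identifiers are exact case-sensitive strings; no alias resolution
  between annotation versions is attempted.
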