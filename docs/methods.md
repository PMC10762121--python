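# Methods

This note records the models, parameter choices and numerical conventions
behind `regulonkit`, and what the synthetic benchmark does and does not
establish.

## Quality control and normalization

Cells are kept when `min_features ≤ detected genes ≤ max_features`
(defaults 500/7,500), `total counts ≥ min_counts` (default 1,000), and
library complexity ≥ 0.8. Complexity defaults to
`log10(features)/log10(counts)`, the standard formulation at that
threshold; the alternative `log2(features/counts)` form is selectable but
degenerate whenever counts ≥ features (it is then never positive), so it
is not the default. Removed cells are reported with the first failed rule
in a fixed rule order (min_features, max_features, min_counts,
complexity). Normalization is the usual depth-scaled log transform
`log(1 + s·x/total)` with scale factor s = 10,000 and natural log by
default (log2 selectable); it preserves within-cell rank order, which is
all the downstream rank-based scores consume.

## Coexpression scoring

`score_edges` treats the edge-importance function as pluggable:

- `abs_spearman` (default): |Spearman ρ| between the TF and every other
  gene. Deterministic, fast, and rank-based, hence invariant to the
  normalization's monotone transform.
- `abs_pearson`: same on the raw normalized values.
- `tree_importance`: per-gene gradient-boosted regression on all TFs
  (scikit-learn; 50 trees, depth 3, subsample 0.8), feature importances
  averaged over `n_runs` runs with seeds derived per run. This mirrors
  the stochastic regression-ensemble family of GRN inference tools; runs
  are combined by mean importance.

The top-ranked network keeps the k highest-importance edges with
deterministic lexicographic tie-breaking. `model.fit` defaults k to
150 × (number of TFs): the cut must be permissive enough to capture a
TF's whole coexpressed program — direct targets *and* co-regulated
bystanders — because the binding intersection, not the edge ranking, is
the precision step. Degree distributions, exact betweenness, and a
log–log least-squares power-law fit (a qualitative scale-free diagnostic,
not a maximum-likelihood tail estimate) summarize network topology.

## Binding targets

BED intervals (0-based half-open) are converted to 1-based inclusive
coordinates on read; TSSs are 1-based. A gene is a high-confidence target
when any peak shares a base with the ±1 kb TSS window — overlap, not
summit containment, because it is the more inclusive reading and is
invariant to splitting a peak into abutting halves. The ±3 kb window
defines promoter-proximal assignments. Reported distance is the peak's
continuous-coordinate midpoint minus the TSS, sign flipped on − strand;
the window itself is symmetric, so strand never changes membership.
Genome coverage uses an endpoint sweep, counting each TF once per base.

## Regulon activity (recovery-curve AUC)

For one cell, rank genes by decreasing normalized expression, ties broken
by one seeded random gene permutation shared across cells (recorded via
the tie seed). With cutoff k = ⌈fraction·G⌉ and hits(x) = number of
regulon genes at rank ≤ x, the activity score is
`Σ_{x≤k} hits(x) / Σ_{x≤k} min(x, |R|)` — observed recovery area over the
maximal area, so the score is exactly 1 when all regulon genes lead the
ranking and 0 when none is in the top k. The default fraction is 0.05;
`explore_thresholds` evaluates the grid {1%, 5%, 10%, 15%, 20%} per
regulon and picks the fraction maximizing either the regulon's best
cluster specificity (`max_top_rss`, default; requires labels) or
across-cell variance, with ties to the smallest fraction. Binarization
z-scores each regulon across cells (sample sd) and calls a cell active
when z exceeds the cutoff (default 0.15, per-regulon overridable);
constant regulons binarize to all zeros.

## Regulon specificity

RSS(R, C) = 1 − √JSD(p_R, p_C): p_R is the regulon's raw (not binarized)
activity normalized to sum 1, p_C the uniform distribution on the
cluster's cells, and JSD the base-2 Jensen–Shannon divergence (scipy),
which is bounded in [0, 1], making RSS a [0, 1] score that is invariant
to positive rescaling of activity. All-zero regulons have no
distribution and are reported missing rather than imputed.

## Regulon modules (CSI)

Activity vectors are compared by Pearson correlation; zero-variance
regulons are flagged and their correlations set to 0. The connection
specificity index of a pair (P, Q) counts third regulons i with
`PCC(P,i) < PCC(P,Q) and PCC(Q,i) < PCC(P,Q)`. Two published forms of
this rule differ in the connective; the disjunctive ("or") form is also
implemented, but it provably inflates weakly correlated pairs whenever
either member has strongly anticorrelated partners — on a noiseless
two-block correlation matrix (within +0.7, across −0.7) it assigns
near-maximal CSI to half the cross-block pairs, scrambling the very
structure the index is meant to expose — so the conjunctive form is the
default. Two normalizations are kept: `fraction` divides by N−2 (scores
in [0, 1], comparable across N, default) and `literal` divides by (N−2)²
(a printed variant whose maximum is 1/(N−2)). Modules come from
complete-linkage clustering on distance = max(CSI) − CSI with the module
count k supplied by the user (defaulting to the number of clusters in
`model.fit`); labels are ordered by module size with id-based
tie-breaking so results are input-order invariant. Module activity is
the plain mean of member-regulon activity per cluster; cluster
relatedness is the Pearson correlation between clusters' mean-activity
profiles with a user threshold for drawing edges.

## Markers, signatures, differentiation score

`find_markers` is a one-vs-rest two-sided Wilcoxon rank-sum test with the
usual pre-filters: detection in ≥ 30% of either population and
|log2 FC| ≥ 0.25, where fold change is computed on `expm1`-means with a
+1 pseudocount. Bonferroni multiplies by the number of genes in the
matrix (the dominant single-cell toolkit's convention);
Benjamini–Hochberg is available for stage contrasts, where
`stage_gene_sets` applies q < 0.05 and |log2 FC| > 2 to split early from
late genes. The gene-signature score is the normalized Mann–Whitney U of
the signature genes' within-cell ranks capped at `r_max` (default 1,500,
the cited method's published default): `max(0, 1 − U/(n·r_max))`,
rank-based and bounded. The cellular differentiation score is
`log2((GSC_late + ε)/(GSC_early + ε))` with ε = 0.01, symmetric at zero
signal.

## Evaluation

Gold-standard pairs missing from a prediction score 0 — an undetected
documented target is a miss, and recall must count it. ROC and PR curves
sweep distinct score thresholds (ties grouped); AUCs are trapezoidal, the
PR curve integrated along the threshold path so duplicate-recall points
contribute zero width. The ROC AUC therefore equals the Mann–Whitney
pair-ordering probability with ties at one half.

## Synthetic data: what it emulates

The generator plants every structure the pipeline assumes: cells in
near-equal contiguous clusters; lognormal baseline expression; negative
binomial counts (size = `nb_dispersion`, default 2) with independent
Bernoulli dropout (default 0.2); TFs with round-robin home clusters whose
targets are upregulated `effect_size`-fold (default 4) at home;
per-cluster background programs (default 25 genes/cluster) that are
coexpressed but unbound — the bystanders that make coexpression-only
inference hard; a synthetic genome (100 genes/chromosome, TSS every
10 kb, alternating strands) whose ±3 kb windows never overlap, so peak
assignment is unambiguous; 200-bp peaks centred uniformly in the ±1 kb
window of true targets with probability `binding_tpr` (0.8) and of
non-targets with `binding_fpr` (0.05); stage markers shifted
`effect_size`-fold between timepoints; and a gold standard whose
positives are exactly the planted edges and whose negatives are unplanted
pairs, drawn half from the TF's home-cluster program (hard negatives,
`hard_negative_fraction` = 0.5) and half uniformly. Defaults are ~2,000
cells, 1,000 genes, 6 clusters, 40 TFs × 20 targets. A single global seed
feeds per-component hash-derived generators, so regenerating one
component never perturbs another and equal seeds give byte-identical
datasets.

Not emulated: ambient RNA, doublets, batch effects, cell-cycle structure,
UMI saturation, gene length or GC biases, chromatin context around peaks.
Passing benchmarks on these data show the pipeline's statistical
machinery is correct and recovers planted structure at realistic noise —
not that inference on real tissue reaches the same accuracy.

## Benchmark problem sizes

The packaged checks use deliberately modest sizes chosen to make the
planted signal estimable with low variance: 20 simulation seeds at the
reference conditions for the integration-vs-coexpression comparison;
600 cells × 400 genes with one TF per cluster for specificity recovery;
800 cells × 500 genes with 12 TFs in two home clusters for module
recovery; 500 cells per stage for the differentiation direction test; and
50 random instances (≤ 30 genes) and 20 random correlation matrices
(≤ 20 regulons) for the exact-oracle comparisons.

## Known limitations

- "Low-quality regulon" filtering beyond the minimum-size rule is not
  operationalized; a user-supplied exclusion list is the only hook.
- The per-regulon threshold-selection criterion (`max_top_rss`) is one
  reasonable reading of "most appropriate"; the grid is persisted so any
  other criterion can be applied post hoc.
- `tree_importance` is O(genes × trees) per run and meant for moderate
  panels, not whole transcriptomes, in this implementation.
- The module count k is user-supplied; no automatic selection is
  attempted.
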