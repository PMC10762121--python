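# regulonkit

Regulon inference and activity scoring for single-cell transcriptomics
combined with transcription-factor binding profiles.

## The problem

A developing tissue — the motivating case is cereal endosperm during cell
differentiation — contains several cell types whose identities are set by
transcription factors (TFs) driving their target genes. Coexpression
networks inferred from scRNA-seq alone confuse direct targets with
co-regulated bystanders: every gene in a cell type's program correlates
with every TF active there. Genome-wide TF-binding assays (DAP-seq,
ChIP-seq) supply the missing direction, but say nothing about *where* a
regulatory interaction is active. `regulonkit` combines the two:

1. **Coexpression edges.** Importance scores for every (TF, gene) pair
   from the log-normalized expression matrix (|Spearman ρ|, |Pearson r|,
   or gradient-boosted regression importances averaged over runs); the
   top-k edges form the coexpression GRN.
2. **Direct binding targets.** A gene is a *high-confidence target* of a
   TF if a binding peak overlaps the ±1 kb window around its TSS
   (peaks beyond that but within ±3 kb are promoter-proximal only).
3. **Regulons.** regulon(TF) = coexpression targets ∩ high-confidence
   binding targets, dropping regulons with fewer than 5 targets.
4. **Regulon activity (RAS).** Per cell, genes are ranked by expression
   and the regulon's recovery curve is walked down to the top fraction
   (default 5%); RAS = observed recovery area / maximal area ∈ [0, 1].
   A z-score cutoff (default 0.15) binarizes activity per regulon.
5. **Regulon specificity (RSS).** RSS(R, C) = 1 − √JSD(p_R, p_C) with
   base-2 Jensen–Shannon divergence between the regulon's normalized
   activity distribution over cells and the cluster indicator
   distribution.
6. **Regulon modules (CSI).** Pairwise Pearson correlation of activity,
   converted to the connection specificity index
   CSI(P, Q) = #{i : PCC(P, i) < PCC(P, Q) and PCC(Q, i) < PCC(P, Q)} / (N−2),
   then complete-linkage clustering into modules; module activity and
   cluster–cluster relatedness summarize the map.
7. **Evaluation.** Predicted networks are scored against gold-standard
   labeled TF–target pairs with ROC and precision–recall curves
   (trapezoidal AUC; the ROC AUC equals the Mann–Whitney pair-ordering
   statistic).

A synthetic-data generator (`regulonkit.simulate`) produces datasets with
this exact statistical structure — clustered negative-binomial counts with
dropout, planted TF→target regulons active in home clusters, per-cluster
background programs, binding peaks at controlled true/false-positive
rates, stage-shifted marker genes, and a consistent gold standard — so the
whole pipeline is testable without downloads.

## Worked example

```python
from regulonkit import SimulationConfig, generate_dataset, RegulonNetworkModel

ds = generate_dataset(SimulationConfig(
    n_cells=1000, n_genes=600, n_clusters=4, n_tfs=12, targets_per_tf=15,
    stage_marker_count=20, background_per_cluster=15, seed=42))
model = RegulonNetworkModel.from_synthetic(ds)
res = model.fit(seed=42)
print(res.summary().head(6))
```

```
         n_targets  mean_activity best_cluster  best_rss module
regulon
TF0001          14       0.038809           C0  0.502055     M1
TF0002          21       0.063869           C1  0.326544     M2
TF0003          17       0.059299           C2  0.384917     M3
TF0004          15       0.069009           C3  0.513426     M4
TF0005          17       0.091262           C0  0.528092     M1
TF0006          13       0.112939           C1  0.434757     M2
```

Each fitted regulon keeps 13–21 of its 15 planted targets plus binding
false positives that survived the intersection; `best_cluster` matches
each TF's planted home cluster, and the detected modules M1–M4 recover the
four home-cluster groups. Evaluating against the planted gold standard:

```python
res.evaluate(ds.gold_edges, mode="binary").auc_roc   # 0.844  (regulons)
res.evaluate(ds.gold_edges, mode="ranked").auc_roc   # 0.697  (coexpression only)
```

The binding intersection lifts ROC AUC because the gold standard's hard
negatives — genes coexpressed with the TF's home-cluster program but never
bound — are exactly what coexpression alone cannot reject.

The same pipeline runs from the shell:

```bash
regulonkit simulate --seed 7 --out demo/
regulonkit run-all --config demo/config.yaml
```

writing per-stage TSV outputs and a checksummed run manifest under
`demo/results/`.

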