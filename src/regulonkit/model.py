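"""Model/Results facade over the regulon-inference pipeline.

:class:`RegulonNetworkModel` is built from the data a study provides — a
QC'd, normalized expression matrix with cluster labels, a TF list, per-TF
binding peaks and a gene annotation — and ``fit()`` runs the inference
chain: coexpression scoring → top-k network → peak-to-TSS target
assignment → regulon intersection and size filtering → per-cell activity →
per-cluster specificity → pairwise CSI and module detection → cluster
relatedness. The returned :class:`RegulonNetworkResults` carries every
intermediate product, a ``summary()`` table, plotting helpers, and
``evaluate()`` against a gold standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData

from . import (activity as _activity, binding as _binding,
               coexpression as _coexpression, evaluation as _evaluation,
               modules as _modules, regulons as _regulons,
               specificity as _specificity)
from ._utils import ValidationError
from .io_qc import LOGNORM_LAYER
from .regulons import RegulonSet


class RegulonNetworkModel:
    """Regulon network inference from expression + TF-binding data.

    Parameters
    ----------
    adata
        Normalized expression (``layers["lognorm"]`` present) with a
        cluster-label column in ``obs``.
    tf_list
        Identifiers of the candidate regulator genes; must be in ``var``.
    peaks
        Mapping TF id -> peak intervals (columns chrom/start/end, BED
        0-based half-open).
    gene_annotation
        Table with gene_id, chrom, tss (1-based), strand.
    cluster_key
        ``obs`` column holding cluster labels.
    """

    def __init__(self, adata: AnnData, tf_list: list[str],
                 peaks: dict[str, pd.DataFrame], gene_annotation: pd.DataFrame,
                 cluster_key: str = "cluster"):
        if LOGNORM_LAYER not in adata.layers:
            raise ValidationError("adata lacks the normalized layer; run normalize()")
        if cluster_key not in adata.obs:
            raise ValidationError(f"obs has no {cluster_key!r} column")
        self.adata = adata
        self.tf_list = list(tf_list)
        self.peaks = peaks
        self.gene_annotation = gene_annotation
        self.cluster_key = cluster_key

    @classmethod
    def from_synthetic(cls, dataset, cluster_key: str = "cluster"
                       ) -> "RegulonNetworkModel":
        """Build a model from a generated dataset (normalizing if needed)."""
        from .io_qc import normalize
        adata = dataset.adata
        if LOGNORM_LAYER not in adata.layers:
            adata = normalize(adata)
        return cls(adata, dataset.tf_ids, dataset.peaks,
                   dataset.gene_annotation, cluster_key=cluster_key)

    def fit(self, method: str = "abs_spearman", n_runs: int = 1,
            n_top_edges: int | None = None, window_bp: int = 1000,
            min_regulon_size: int = 5, threshold_fraction: float = 0.05,
            binarize_cutoff: float = 0.15, n_modules: int | None = None,
            relatedness_threshold: float = 0.0, seed: int = 0,
            edges: pd.DataFrame | None = None) -> "RegulonNetworkResults":
        """Run the full inference chain and return a results object.

        ``n_top_edges`` defaults to 150 × the number of TFs: a deliberately
        permissive cut sized to capture each TF's whole coexpressed program
        (direct targets plus co-regulated bystanders); the binding
        intersection does the sharpening.
        ``n_modules`` defaults to the number of clusters. A precomputed
        ``edges`` table (tf, target, importance) skips coexpression scoring.
        """
        if edges is None:
            edges = _coexpression.score_edges(self.adata, self.tf_list,
                                              method=method, n_runs=n_runs,
                                              seed=seed)
        if n_top_edges is None:
            n_top_edges = 150 * len(self.tf_list)
        top = _coexpression.top_k_edges(edges, n_top_edges)
        targets = _binding.assign_targets(self.peaks, self.gene_annotation,
                                          window_bp=window_bp)
        raw_regulons = _regulons.build_regulons(top, targets)
        regulon_set, dropped = _regulons.filter_regulons(raw_regulons,
                                                         min_size=min_regulon_size)
        act = _activity.ras_matrix(self.adata, regulon_set,
                                   threshold_fraction=threshold_fraction,
                                   tie_seed=seed)
        act = _activity.binarize(act, cutoff=binarize_cutoff)
        clusters = self.adata.obs[self.cluster_key]
        rss_matrix = _specificity.rss(act, clusters)

        pcc = csi_matrix = module_labels = module_scores = None
        relatedness = relatedness_edges = None
        if len(regulon_set) >= 3:
            pcc = _modules.regulon_pcc(act)
            csi_matrix = _modules.csi(pcc)
            k = n_modules if n_modules is not None else clusters.nunique()
            k = min(k, len(regulon_set))
            module_labels = _modules.detect_modules(csi_matrix, k)
            module_scores = _modules.module_activity(act, module_labels, clusters)
        if clusters.nunique() >= 2:
            relatedness, relatedness_edges = _modules.cluster_relatedness(
                act, clusters, edge_threshold=relatedness_threshold)

        return RegulonNetworkResults(
            model=self, edges=edges, top_edges=top, target_assignments=targets,
            regulons=regulon_set, dropped_regulons=dropped, activity=act,
            rss=rss_matrix, pcc=pcc, csi=csi_matrix, modules=module_labels,
            module_activity=module_scores, cluster_relatedness=relatedness,
            relatedness_edges=relatedness_edges,
            params={"method": method, "n_runs": n_runs, "n_top_edges": n_top_edges,
                    "window_bp": window_bp, "min_regulon_size": min_regulon_size,
                    "threshold_fraction": threshold_fraction,
                    "binarize_cutoff": binarize_cutoff, "seed": seed})


@dataclass
class RegulonNetworkResults:
    """Fitted regulon network: all stage outputs plus reporting helpers."""

    model: RegulonNetworkModel = field(repr=False)
    edges: pd.DataFrame = field(repr=False)
    top_edges: pd.DataFrame = field(repr=False)
    target_assignments: pd.DataFrame = field(repr=False)
    regulons: RegulonSet
    dropped_regulons: pd.DataFrame = field(repr=False)
    activity: _activity.ActivityMatrix = field(repr=False)
    rss: pd.DataFrame = field(repr=False)
    pcc: pd.DataFrame | None = field(repr=False, default=None)
    csi: pd.DataFrame | None = field(repr=False, default=None)
    modules: pd.Series | None = None
    module_activity: pd.DataFrame | None = field(repr=False, default=None)
    cluster_relatedness: pd.DataFrame | None = field(repr=False, default=None)
    relatedness_edges: pd.DataFrame | None = field(repr=False, default=None)
    params: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Per-regulon summary: size, mean activity, best cluster, module."""
        rows = []
        for tf in self.regulons.tfs:
            rss_row = self.rss.loc[tf]
            best = rss_row.idxmax() if rss_row.notna().any() else None
            rows.append({
                "regulon": tf,
                "n_targets": len(self.regulons.table(tf)),
                "mean_activity": float(self.activity.ras.loc[tf].mean()),
                "best_cluster": best,
                "best_rss": float(rss_row.max()) if best is not None else np.nan,
                "module": (self.modules.get(tf) if self.modules is not None
                           else None),
            })
        return pd.DataFrame(rows).set_index("regulon")

    def top_regulons(self, n: int = 5) -> pd.DataFrame:
        return _specificity.top_regulons_per_cluster(self.rss, n=n)

    def evaluate(self, gold: pd.DataFrame, mode: str = "binary"
                 ) -> _evaluation.EvaluationResult:
        """ROC/PR of the fitted network against a labeled edge table.

        ``binary`` scores regulon membership; ``ranked`` scores the
        underlying coexpression importances.
        """
        predicted = self.regulons if mode == "binary" else self.edges
        scored = _evaluation.score_predictions(predicted, gold, mode=mode)
        return _evaluation.roc_pr(scored)

    def plot_rss(self, cluster, ax=None, n_label: int = 5):
        """Rank plot of regulon specificity for one cluster."""
        import matplotlib.pyplot as plt

        col = self.rss[cluster].dropna().sort_values(ascending=False)
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        ax.plot(np.arange(1, len(col) + 1), col.to_numpy(), ".", ms=4)
        for i, (reg, val) in enumerate(col.head(n_label).items()):
            ax.annotate(reg, (i + 1, val), fontsize=7)
        ax.set_xlabel("regulon rank")
        ax.set_ylabel("specificity (RSS)")
        ax.set_title(f"cluster {cluster}")
        return ax
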