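"""Marker detection, rank-based signature scores, differentiation score.

Marker genes are called one group against the rest with a two-sided
Wilcoxon rank-sum test after the usual detection-rate and fold-change
pre-filters. Signature scores are the normalized Mann–Whitney U statistic
of a gene set's within-cell ranks (capped at ``r_max``), so they live in
[0, 1] and depend only on ranks. The cellular differentiation score is the
log2 ratio of a cell's late-stage to early-stage signature scores.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy.stats import mannwhitneyu, rankdata

from ._utils import ValidationError
from .coexpression import _dense_lognorm

MARKER_COLUMNS = ["gene_id", "group", "log_fc", "pct_in", "pct_out",
                  "p_value", "p_adjusted"]


def find_markers(adata: AnnData, groups: pd.Series, min_pct: float = 0.3,
                 logfc_threshold: float = 0.25, correction: str = "bonferroni"
                 ) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker test per group.

    Genes enter the test when detected in at least ``min_pct`` of either
    population and when |log2 fold change| >= ``logfc_threshold``, with
    log_fc = log2((mean expm1(normalized) + 1) in / out). P-values are
    two-sided rank-sum; Bonferroni adjustment multiplies by the number of
    genes in the matrix (the convention of the single-cell toolkits this
    mirrors). Groups with fewer than 3 cells are skipped with a warning.
    """
    values = _dense_lognorm(adata)
    groups = pd.Series(groups).loc[adata.obs_names]
    if groups.nunique() < 2:
        raise ValidationError("find_markers needs >= 2 groups")
    n_total_genes = adata.n_vars
    rows = []
    for group in sorted(groups.unique()):
        in_mask = (groups == group).to_numpy()
        if in_mask.sum() < 3:
            warnings.warn(f"group {group}: fewer than 3 cells, skipped", stacklevel=2)
            continue
        v_in, v_out = values[in_mask], values[~in_mask]
        pct_in = (v_in > 0).mean(axis=0)
        pct_out = (v_out > 0).mean(axis=0)
        log_fc = np.log2((np.expm1(v_in).mean(axis=0) + 1)
                         / (np.expm1(v_out).mean(axis=0) + 1))
        tested = (np.maximum(pct_in, pct_out) >= min_pct) \
            & (np.abs(log_fc) >= logfc_threshold)
        for j in np.flatnonzero(tested):
            p = mannwhitneyu(v_in[:, j], v_out[:, j], alternative="two-sided",
                             method="auto").pvalue
            rows.append((adata.var_names[j], group, float(log_fc[j]),
                         float(pct_in[j]), float(pct_out[j]), float(p),
                         min(1.0, float(p) * n_total_genes)))
    table = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests
        if not table.empty:
            table["p_adjusted"] = multipletests(table["p_value"], method="fdr_bh")[1]
    elif correction != "bonferroni":
        raise ValidationError(f"unknown correction {correction!r}")
    return table


def stage_gene_sets(marker_table: pd.DataFrame, late_group: str = "late",
                    fdr: float = 0.05, abs_lfc: float = 2.0
                    ) -> tuple[set[str], set[str]]:
    """Early/late stage gene sets from a two-group marker table.

    Within the late-group rows, q-values are Benjamini–Hochberg adjusted
    p-values; the late set takes q < fdr and log_fc > abs_lfc, the early
    set q < fdr and log_fc < −abs_lfc (fold changes are signed with the
    early stage as the reference).
    """
    from statsmodels.stats.multitest import multipletests

    sub = marker_table[marker_table["group"] == late_group]
    if sub.empty:
        raise ValidationError(f"no rows for group {late_group!r}")
    q = multipletests(sub["p_value"], method="fdr_bh")[1]
    sub = sub.assign(q_value=q)
    late = set(sub.loc[(sub["q_value"] < fdr) & (sub["log_fc"] > abs_lfc), "gene_id"])
    early = set(sub.loc[(sub["q_value"] < fdr) & (sub["log_fc"] < -abs_lfc), "gene_id"])
    if not late and not early:
        raise ValidationError(
            "no stage-specific genes at these thresholds; relax fdr or abs_lfc")
    return early, late


def signature_score(adata: AnnData, gene_set: set[str] | list[str],
                    r_max: int = 1500) -> pd.Series:
    """Per-cell rank-based gene-set score (normalized Mann–Whitney U).

    Genes are ranked by decreasing expression within each cell (average
    ranks on ties); signature-gene ranks above ``r_max`` are capped at
    r_max + 1. With n signature genes, U = Σ ranks − n(n+1)/2 and
    score = max(0, 1 − U / (n · r_max)): 1 when every signature gene is
    top-ranked, 0 when all lie beyond the cap.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValidationError("gene_set is empty")
    present = [g for g in adata.var_names if g in gene_set]
    if not present:
        raise ValidationError("no signature gene present in the matrix")
    values = _dense_lognorm(adata)
    ranks = rankdata(-values, axis=1, method="average")
    cols = [adata.var_names.get_loc(g) for g in present]
    r = np.minimum(ranks[:, cols], r_max + 1)
    n = len(present)
    u = r.sum(axis=1) - n * (n + 1) / 2.0
    score = np.maximum(0.0, 1.0 - u / (n * r_max))
    return pd.Series(score, index=adata.obs_names, name="signature_score")


def differentiation_score(gsc_early: pd.Series, gsc_late: pd.Series,
                          pseudocount: float = 0.01) -> pd.Series:
    """log2((late + pseudocount) / (early + pseudocount)) per cell.

    Positive values mark cells whose transcriptome leans late-stage. The
    pseudocount keeps the ratio finite and symmetric at zero scores.
    """
    early, late = gsc_early.align(gsc_late, join="inner")
    return pd.Series(np.log2((late + pseudocount) / (early + pseudocount)),
                     index=early.index, name="differentiation_score")
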