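"""Regulon specificity scores from Jensen–Shannon divergence.

A regulon's activity vector over cells, normalized to sum to one, is
compared against the indicator distribution of a cell cluster (uniform on
the cluster's cells, zero elsewhere). With base-2 entropy the divergence
lies in [0, 1]; the specificity score is 1 − sqrt(JSD), so a regulon
active uniformly on exactly the cluster's cells scores 1 and one active
only outside it scores 0.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from ._utils import ValidationError
from .activity import ActivityMatrix


def rss(activity: ActivityMatrix, clusters: pd.Series) -> pd.DataFrame:
    """Specificity of every regulon for every cluster.

    ``clusters`` maps cell id -> cluster label and must cover every cell in
    the activity matrix. Regulons whose activity is all zero have no
    distribution to compare and are recorded as NaN with a warning.
    Scores are invariant to positive rescaling of a regulon's activity.
    """
    ras = activity.ras
    clusters = pd.Series(clusters)
    missing = [c for c in ras.columns if c not in clusters.index]
    if missing:
        raise ValidationError(f"cells without cluster label: {missing[:5]}...")
    labels = clusters.loc[ras.columns]
    cluster_ids = sorted(labels.unique())

    out = pd.DataFrame(index=ras.index, columns=cluster_ids, dtype=float)
    indicator = {}
    for cl in cluster_ids:
        ind = (labels == cl).to_numpy(dtype=float)
        indicator[cl] = ind / ind.sum()
    totals = ras.sum(axis=1)
    for reg in ras.index:
        total = totals.loc[reg]
        if total == 0:
            warnings.warn(f"regulon {reg}: all-zero activity, RSS undefined",
                          stacklevel=2)
            continue
        p_r = ras.loc[reg].to_numpy() / total
        for cl in cluster_ids:
            # scipy returns sqrt(JSD) directly for the chosen log base
            out.loc[reg, cl] = 1.0 - jensenshannon(p_r, indicator[cl], base=2)
    return out


def top_regulons_per_cluster(rss_matrix: pd.DataFrame, n: int = 5) -> pd.DataFrame:
    """Rank regulons within each cluster by descending specificity.

    Ties break lexicographically by regulon id. Returns a long table
    (cluster, rank, regulon, rss) with at most ``n`` rows per cluster; if
    ``n`` exceeds the number of regulons the full ranking is returned.
    """
    rows = []
    for cl in rss_matrix.columns:
        col = rss_matrix[cl].dropna()
        ordered = col.sort_index().sort_values(ascending=False, kind="mergesort")
        for rank, (reg, value) in enumerate(ordered.head(n).items(), start=1):
            rows.append((cl, rank, reg, float(value)))
    return pd.DataFrame(rows, columns=["cluster", "rank", "regulon", "rss"])
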