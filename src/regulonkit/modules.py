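"""Regulon modules: pairwise correlation, connection specificity, clustering.

The connection specificity index (CSI) of a regulon pair (P, Q) asks how
many other regulons i are *less* correlated with both P and Q than P and
Q are with each other; a high CSI marks a specifically associated pair
rather than two members of one broadly correlated block. Two normalizations are
provided: ``fraction`` divides the count by (N − 2), giving a score in
[0, 1]; ``literal`` divides by (N − 2)², the form printed in the source
method description (whose maximum is then 1/(N − 2)). The fraction variant
is the default because scores stay comparable across regulon-set sizes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._utils import ValidationError
from .activity import ActivityMatrix


def regulon_pcc(activity: ActivityMatrix) -> pd.DataFrame:
    """Pearson correlation of activity vectors for every regulon pair.

    Zero-variance regulons correlate with nothing; their entries are
    recorded as 0 (diagonal stays 1) with a warning.
    """
    ras = activity.ras
    if len(ras) < 2 or ras.shape[1] < 3:
        raise ValidationError("regulon_pcc needs >= 2 regulons and >= 3 cells")
    values = ras.to_numpy(dtype=float)
    sd = values.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"zero-variance regulons {list(ras.index[degenerate])}: PCC set to 0",
            stacklevel=2)
    safe = values.copy()
    safe[degenerate] = np.random.default_rng(0).normal(size=(int(degenerate.sum()),
                                                             values.shape[1]))
    corr = np.corrcoef(safe)
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=ras.index, columns=ras.index)


def csi(pcc_matrix: pd.DataFrame, variant: str = "fraction",
        connective: str = "and") -> pd.DataFrame:
    """Connection specificity index for every regulon pair.

    With ``connective="and"`` (default, the established definition),
    i ∉ {P, Q} counts iff PCC(P, i) < PCC(P, Q) and PCC(Q, i) < PCC(P, Q):
    a pair is specific when *no* third regulon is as correlated with either
    member. ``connective="or"`` counts i when either inequality holds — a
    variant sometimes printed in the literature, kept for fidelity; note it
    inflates the score of weakly correlated pairs whenever one member has
    strongly anticorrelated partners, which scrambles block structure.
    ``fraction`` divides the count by (N − 2); ``literal`` by (N − 2)².
    Symmetric by construction; the diagonal is excluded from the sums and
    reported as the variant's maximum.
    """
    if variant not in ("fraction", "literal"):
        raise ValidationError(f"unknown variant {variant!r}")
    if connective not in ("and", "or"):
        raise ValidationError(f"unknown connective {connective!r}")
    C = pcc_matrix.to_numpy(dtype=float)
    N = C.shape[0]
    if N < 3:
        raise ValidationError("CSI undefined for fewer than 3 regulons")
    denom = (N - 2) if variant == "fraction" else (N - 2) ** 2
    op = np.logical_and if connective == "and" else np.logical_or
    out = np.zeros_like(C)
    for a in range(N):
        for b in range(a + 1, N):
            c_ab = C[a, b]
            m = op(C[a] < c_ab, C[b] < c_ab)
            m[a] = m[b] = False
            out[a, b] = out[b, a] = m.sum() / denom
    np.fill_diagonal(out, (N - 2) / denom)
    df = pd.DataFrame(out, index=pcc_matrix.index, columns=pcc_matrix.columns)
    df.attrs["variant"] = variant
    df.attrs["connective"] = connective
    return df


def detect_modules(csi_matrix: pd.DataFrame, k: int) -> pd.Series:
    """Cut a complete-linkage tree on the CSI into k modules.

    Distance between regulons = (max CSI − CSI). Labels M1..Mk are ordered
    by descending module size (ties by smallest member id), so the labeling
    is invariant to input row order.
    """
    N = len(csi_matrix)
    if not 1 <= k <= N:
        raise ValidationError(f"k must be in [1, {N}], got {k}")
    order = np.argsort(csi_matrix.index)
    ordered = csi_matrix.iloc[order, order]  # stable tie-breaking by id
    dist = ordered.to_numpy(dtype=float).max() - ordered.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    z = linkage(squareform(dist, checks=False), method="complete")
    raw = fcluster(z, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=ordered.index)
    groups = sorted(labels.groupby(labels).groups.items(),
                    key=lambda kv: (-len(kv[1]), sorted(kv[1])[0]))
    rename = {old: f"M{i + 1}" for i, (old, _) in enumerate(groups)}
    return labels.map(rename).reindex(csi_matrix.index).rename("module")


def module_activity(activity: ActivityMatrix, modules: pd.Series,
                    clusters: pd.Series) -> pd.DataFrame:
    """Mean activity of each module's member regulons within each cluster.

    score(M, C) = mean over member regulons and cells of cluster C of the
    activity score; size-weighted cluster averages therefore recover each
    module's global mean activity.
    """
    ras = activity.ras
    clusters = pd.Series(clusters).loc[ras.columns]
    rows = {}
    for mod, members in modules.groupby(modules).groups.items():
        members = [m for m in members if m in ras.index]
        if not members:
            warnings.warn(f"module {mod} has no regulons in the activity matrix",
                          stacklevel=2)
            continue
        sub = ras.loc[members]
        rows[mod] = sub.T.groupby(clusters, observed=True).mean().mean(axis=1)
    return pd.DataFrame(rows).T.sort_index()


def cluster_relatedness(activity: ActivityMatrix, clusters: pd.Series,
                        edge_threshold: float = 0.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster–cluster similarity from mean regulon activity profiles.

    Each cluster is summarized by its mean activity per regulon; clusters
    are compared by Pearson correlation, and edges with PCC >= threshold
    are returned alongside the full matrix.
    """
    ras = activity.ras
    clusters = pd.Series(clusters).loc[ras.columns]
    profile = ras.T.groupby(clusters, observed=True).mean()  # clusters x regulons
    if len(profile) < 2:
        raise ValidationError("cluster_relatedness needs >= 2 clusters")
    corr = pd.DataFrame(np.corrcoef(profile.to_numpy(dtype=float)),
                        index=profile.index, columns=profile.index)
    edges = []
    ids = list(corr.index)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if corr.loc[a, b] >= edge_threshold:
                edges.append((a, b, float(corr.loc[a, b])))
    return corr, pd.DataFrame(edges, columns=["cluster_a", "cluster_b", "pcc"])
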