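"""Per-cell regulon activity as recovery-curve AUC, and binarization.

For one cell, genes are ranked by decreasing expression (1 = highest).
Walking down the ranking to a cutoff k = ceil(threshold_fraction * G), the
recovery curve counts how many regulon genes have been seen at each step;
the activity score is the observed area under that curve divided by the
maximal achievable area (all regulon genes at the very top), so it lies in
[0, 1], equals 1 when every regulon gene is top-ranked, and 0 when none is
within the top k. It depends only on within-cell ranks, hence is invariant
to any monotone transform of the expression values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData

from ._utils import ValidationError, derive_seed
from .coexpression import _dense_lognorm
from .regulons import RegulonSet


@dataclass
class ActivityMatrix:
    """Regulons × cells activity scores with an optional binarized layer."""

    ras: pd.DataFrame
    threshold_fraction: pd.Series
    binarized: pd.DataFrame | None = None
    binarization_cutoff: pd.Series | None = None
    tie_seed: int | None = field(default=None, repr=False)

    @property
    def regulon_ids(self) -> list[str]:
        return list(self.ras.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.ras.columns)


def _max_area(k: int, m: int) -> float:
    """Σ_{x=1..k} min(x, m): maximal recovery area for m set genes, cutoff k."""
    if k <= m:
        return k * (k + 1) / 2.0
    return m * (m + 1) / 2.0 + (k - m) * m


def ras_cell(ranks, regulon_genes, threshold_fraction: float) -> float:
    """Recovery-curve AUC for one cell.

    ``ranks``: mapping or Series gene -> rank, a permutation of 1..G with
    ties already broken. A set gene at rank r <= k contributes (k - r + 1)
    to the observed area.
    """
    if not 0.0 < threshold_fraction <= 1.0:
        raise ValidationError("threshold_fraction must be in (0, 1]")
    if len(regulon_genes) == 0:
        raise ValidationError("regulon_genes is empty")
    ranks = pd.Series(ranks)
    present = [g for g in regulon_genes if g in ranks.index]
    if len(present) < len(regulon_genes):
        warnings.warn("regulon genes absent from matrix were excluded", stacklevel=2)
    if not present:
        raise ValidationError("no regulon gene present in the ranking")
    G = len(ranks)
    k = int(np.ceil(threshold_fraction * G))
    r = ranks.loc[present].to_numpy()
    observed = float(np.sum(np.maximum(k - r + 1, 0)))
    return observed / _max_area(k, len(present))


def _rank_matrix(adata: AnnData, tie_seed: int) -> np.ndarray:
    """Per-cell dense ranks (1 = highest expression), ties broken by one
    seeded random gene permutation shared across cells."""
    values = _dense_lognorm(adata)
    n_cells, n_genes = values.shape
    tiebreak = np.random.default_rng(derive_seed(tie_seed, "ras_ties")).permutation(n_genes)
    ranks = np.empty((n_cells, n_genes), dtype=np.int64)
    rows = np.arange(n_genes)
    for c in range(n_cells):
        order = np.lexsort((tiebreak, -values[c]))
        ranks[c, order] = rows + 1
    return ranks


def ras_matrix(adata: AnnData, regulons: RegulonSet,
               threshold_fraction: float | pd.Series = 0.05,
               tie_seed: int = 0) -> ActivityMatrix:
    """Activity scores for every (regulon, cell).

    Per-cell rankings are computed once and reused across regulons.
    ``threshold_fraction`` may be a scalar or a per-regulon Series.
    """
    ranks = _rank_matrix(adata, tie_seed)
    G = adata.n_vars
    var_pos = {g: j for j, g in enumerate(adata.var_names)}
    if np.isscalar(threshold_fraction):
        fractions = pd.Series(float(threshold_fraction), index=regulons.tfs)
    else:
        fractions = pd.Series(threshold_fraction).reindex(regulons.tfs)
        if fractions.isna().any():
            raise ValidationError("threshold_fraction missing for some regulons")
    scores = np.zeros((len(regulons), adata.n_obs))
    for i, tf in enumerate(regulons.tfs):
        genes = regulons.targets(tf)
        if not genes:
            raise ValidationError(f"regulon {tf} is empty")
        cols = [var_pos[g] for g in genes if g in var_pos]
        if len(cols) < len(genes):
            warnings.warn(f"regulon {tf}: genes absent from matrix excluded",
                          stacklevel=2)
        if not cols:
            raise ValidationError(f"regulon {tf}: no gene present in matrix")
        f = float(fractions.loc[tf])
        if not 0.0 < f <= 1.0:
            raise ValidationError("threshold_fraction must be in (0, 1]")
        k = int(np.ceil(f * G))
        r = ranks[:, cols]
        observed = np.maximum(k - r + 1, 0).sum(axis=1)
        scores[i] = observed / _max_area(k, len(cols))
    ras = pd.DataFrame(scores, index=regulons.tfs, columns=adata.obs_names)
    return ActivityMatrix(ras=ras, threshold_fraction=fractions, tie_seed=tie_seed)


DEFAULT_FRACTIONS = (0.01, 0.05, 0.10, 0.15, 0.20)


def explore_thresholds(adata: AnnData, regulons: RegulonSet,
                       fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
                       criterion: str = "max_top_rss",
                       clusters: pd.Series | None = None,
                       tie_seed: int = 0) -> tuple[pd.Series, pd.DataFrame]:
    """Choose a rank-cutoff fraction per regulon from a grid.

    ``max_top_rss`` picks the fraction maximizing the regulon's best
    cluster specificity (needs cluster labels); ``max_variance`` the
    fraction maximizing across-cell activity variance. Ties go to the
    smallest fraction. Returns the per-regulon choice and the full grid.
    """
    from .specificity import rss as _rss

    if criterion not in ("max_top_rss", "max_variance"):
        raise ValidationError(f"unknown criterion {criterion!r}")
    if criterion == "max_top_rss" and clusters is None:
        raise ValidationError("max_top_rss requires cluster labels")
    grid = []
    for f in fractions:
        act = ras_matrix(adata, regulons, threshold_fraction=f, tie_seed=tie_seed)
        if criterion == "max_variance":
            stat = act.ras.var(axis=1, ddof=1)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat = _rss(act, clusters).max(axis=1)
        grid.append(stat.rename(f))
    grid_df = pd.concat(grid, axis=1)
    # idxmax on columns ordered ascending returns the smallest tied fraction
    chosen = grid_df.fillna(-np.inf).idxmax(axis=1).astype(float)
    return chosen, grid_df


def binarize(activity: ActivityMatrix, cutoff: float | pd.Series = 0.15
             ) -> ActivityMatrix:
    """Threshold z-scored activity into on/off calls.

    Per regulon, z = (ras − mean over cells) / sd (ddof=1); a cell is "on"
    iff z > cutoff. Zero-variance regulons binarize to all zeros. ``cutoff``
    may be per-regulon.
    """
    ras = activity.ras
    if np.isscalar(cutoff):
        cutoffs = pd.Series(float(cutoff), index=ras.index)
    else:
        cutoffs = pd.Series(cutoff).reindex(ras.index)
        if cutoffs.isna().any():
            raise ValidationError("binarization cutoff missing for some regulons")
    mean = ras.mean(axis=1)
    sd = ras.std(axis=1, ddof=1)
    constant = (ras.max(axis=1) - ras.min(axis=1)) == 0  # exact, unlike sd
    z = ras.sub(mean, axis=0).div(sd.where(~constant, np.inf), axis=0)
    binarized = z.gt(cutoffs, axis=0).astype(np.int8)
    binarized.loc[constant] = 0  # degenerate regulons carry no signal
    activity.binarized = binarized
    activity.binarization_cutoff = cutoffs
    return activity
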