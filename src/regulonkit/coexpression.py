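"""TF→gene coexpression scoring, top-k network extraction, topology.

The edge list is a DataFrame with columns (tf, target, importance) and a
``.attrs`` record of the scoring method and number of averaged runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from anndata import AnnData
from scipy.stats import rankdata

from ._utils import ValidationError, derive_seed
from .io_qc import LOGNORM_LAYER

EDGE_COLUMNS = ["tf", "target", "importance"]


def _dense_lognorm(adata: AnnData) -> np.ndarray:
    if LOGNORM_LAYER not in adata.layers:
        raise ValidationError("normalized layer missing; run normalize() first")
    layer = adata.layers[LOGNORM_LAYER]
    return np.asarray(layer.todense()) if hasattr(layer, "todense") else np.asarray(layer)


def _abs_corr(values: np.ndarray, tf_cols: np.ndarray) -> np.ndarray:
    """|Pearson| of each TF column against every gene column; NaN-safe 0."""
    centred = values - values.mean(axis=0)
    sd = centred.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = centred / sd_safe
    corr = z[:, tf_cols].T @ z / values.shape[0]
    corr[:, :] = np.where(sd[None, :] == 0, 0.0, corr)
    corr = np.where(sd[tf_cols, None] == 0, 0.0, corr)
    return np.abs(corr)


def score_edges(adata: AnnData, tf_list: list[str], method: str = "abs_spearman",
                n_runs: int = 1, seed: int = 0, tree_kwargs: dict | None = None
                ) -> pd.DataFrame:
    """Score every (TF, gene≠TF) pair.

    Methods: ``abs_spearman`` and ``abs_pearson`` (deterministic, absolute
    correlation of the normalized layer) and ``tree_importance``
    (gradient-boosted regression of each gene on all TFs, importance
    averaged over ``n_runs`` independently seeded runs — the stochastic
    regression-ensemble family the field's GRN inference tools use).
    """
    missing = [tf for tf in tf_list if tf not in adata.var_names]
    if missing:
        raise ValidationError(f"TFs absent from matrix: {missing}")
    if not tf_list:
        raise ValidationError("tf_list is empty")
    values = _dense_lognorm(adata)
    genes = np.asarray(adata.var_names)
    tf_cols = np.array([adata.var_names.get_loc(tf) for tf in tf_list])

    if method in ("abs_spearman", "abs_pearson"):
        data = rankdata(values, axis=0) if method == "abs_spearman" else values
        imp = _abs_corr(data, tf_cols)
    elif method == "tree_importance":
        imp = np.zeros((len(tf_list), len(genes)))
        for r in range(n_runs):
            imp += _tree_importance_run(values, tf_cols,
                                        derive_seed(seed, f"tree_run_{r}"),
                                        tree_kwargs or {})
        imp /= n_runs
    else:
        raise ValidationError(f"unknown method {method!r}")

    rows = []
    for i, tf in enumerate(tf_list):
        for j, gene in enumerate(genes):
            if gene == tf:
                continue
            rows.append((tf, gene, float(imp[i, j])))
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    edges.attrs["method"] = method
    edges.attrs["n_runs"] = n_runs if method == "tree_importance" else 1
    return edges


def _tree_importance_run(values: np.ndarray, tf_cols: np.ndarray, seed: int,
                         tree_kwargs: dict) -> np.ndarray:
    from sklearn.ensemble import GradientBoostingRegressor

    kwargs = {"n_estimators": 50, "max_depth": 3, "subsample": 0.8,
              "max_features": "sqrt", "random_state": seed}
    kwargs.update(tree_kwargs)
    n_genes = values.shape[1]
    X = values[:, tf_cols]
    imp = np.zeros((len(tf_cols), n_genes))
    tf_pos = {c: i for i, c in enumerate(tf_cols)}
    for j in range(n_genes):
        y = values[:, j]
        if np.all(y == y[0]):
            continue
        mask = np.ones(len(tf_cols), dtype=bool)
        if j in tf_pos:
            mask[tf_pos[j]] = False
        model = GradientBoostingRegressor(**kwargs)
        model.fit(X[:, mask], y)
        imp[mask, j] = model.feature_importances_
    return imp


def top_k_edges(edges: pd.DataFrame, k: int) -> pd.DataFrame:
    """The k highest-importance edges, deterministically.

    Ties at the boundary break by (tf, target) lexicographic order, so the
    output is invariant to input record order.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    ordered = edges.sort_values(["importance", "tf", "target"],
                                ascending=[False, True, True], kind="mergesort")
    if k > len(edges):
        import warnings
        warnings.warn(f"k={k} exceeds number of edges ({len(edges)}); returning all",
                      stacklevel=2)
        k = len(edges)
    out = ordered.head(k).reset_index(drop=True)
    out.attrs = dict(edges.attrs)
    return out


def topology(edges: pd.DataFrame, normalized_betweenness: bool = False) -> dict:
    """Degree, betweenness, and power-law summaries of a directed network.

    Betweenness is exact shortest-path counting (unnormalized by default).
    The power-law check is a least-squares fit of log10(frequency) against
    log10(degree) over total degrees >= 1 — a qualitative scale-free
    diagnostic, not a maximum-likelihood tail fit.
    """
    if edges.empty:
        raise ValidationError("topology requires a non-empty edge list")
    g = nx.DiGraph()
    g.add_edges_from(edges[["tf", "target"]].itertuples(index=False, name=None))
    out_degree = pd.Series(dict(g.out_degree()), name="out_degree")
    in_degree = pd.Series(dict(g.in_degree()), name="in_degree")
    betweenness = pd.Series(
        nx.betweenness_centrality(g, normalized=normalized_betweenness),
        name="betweenness")

    degree = (out_degree + in_degree).astype(int)
    counts = degree[degree >= 1].value_counts()
    if len(counts) >= 2:
        x = np.log10(counts.index.to_numpy(dtype=float))
        y = np.log10(counts.to_numpy(dtype=float))
        slope, intercept = np.polyfit(x, y, 1)
        fitted = slope * x + intercept
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    else:
        slope, r2 = np.nan, np.nan
    nodes = pd.DataFrame({"out_degree": out_degree, "in_degree": in_degree,
                          "betweenness": betweenness}).fillna(0)
    return {"nodes": nodes, "power_law_slope": float(slope),
            "power_law_r2": float(r2) if r2 == r2 else np.nan}
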