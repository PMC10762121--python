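"""Count-matrix I/O, cell quality control, and log-normalization.

The in-memory container is :class:`anndata.AnnData`: cells on ``obs``,
genes on ``var``, raw counts in ``X`` and the log-normalized layer in
``layers["lognorm"]``.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.io import mmread, mmwrite

from ._utils import ValidationError

LOGNORM_LAYER = "lognorm"


class FormatError(ValueError):
    """Malformed input file."""


from dataclasses import dataclass


@dataclass
class QCThresholds:
    """Cell-level QC rules.

    Cells are retained when min_features <= features <= max_features,
    total counts >= min_counts, and library complexity >= min_complexity.
    ``complexity_mode``:

    - ``log10_ratio`` (default): log10(features) / log10(counts) — the
      standard complexity filter.
    - ``log2_ratio``: log2(features / counts) — degenerate whenever
      counts >= features (then it is never positive), provided only for
      protocol fidelity.
    """

    min_features: int = 500
    max_features: int = 7500
    min_counts: int = 1000
    min_complexity: float = 0.8
    complexity_mode: str = "log10_ratio"

    def __post_init__(self):
        if self.min_features >= self.max_features:
            raise ValidationError("min_features must be < max_features")
        if self.min_counts < 0:
            raise ValidationError("min_counts must be >= 0")
        if self.complexity_mode not in ("log10_ratio", "log2_ratio"):
            raise ValidationError(f"unknown complexity_mode {self.complexity_mode!r}")


def read_matrix(path: str | Path, fmt: str = "mtx_triplet",
                cells_as_rows: bool = True) -> AnnData:
    """Read a count matrix into AnnData.

    ``mtx_triplet`` expects ``matrix.mtx`` with ``barcodes.tsv`` and
    ``features.tsv`` sidecars in the same directory (or ``path`` being that
    directory); duplicate triplet entries sum, per the MatrixMarket
    convention. ``dense_tsv`` expects cells in rows, genes in columns, with
    header and index. ``cells_as_rows=False`` declares gene-major
    orientation for MatrixMarket input; orientation is never guessed.
    """
    path = Path(path)
    if fmt == "mtx_triplet":
        base = path if path.is_dir() else path.parent
        mtx = path if path.suffix == ".mtx" else base / "matrix.mtx"
        try:
            m = mmread(mtx)
        except Exception as exc:  # scipy raises assorted ValueError subtypes
            raise FormatError(f"cannot parse MatrixMarket file {mtx}: {exc}") from exc
        m = sp.csr_matrix(m)
        if (m.data < 0).any():
            raise FormatError(f"negative counts in {mtx}")
        if not cells_as_rows:
            m = m.T.tocsr()
        barcodes = pd.read_csv(base / "barcodes.tsv", header=None)[0].astype(str)
        features = pd.read_csv(base / "features.tsv", header=None, sep="\t")[0].astype(str)
        if m.shape != (len(barcodes), len(features)):
            raise FormatError(
                f"matrix shape {m.shape} does not match {len(barcodes)} barcodes"
                f" x {len(features)} features")
        adata = AnnData(X=m, obs=pd.DataFrame(index=barcodes.tolist()),
                        var=pd.DataFrame(index=features.tolist()))
    elif fmt == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if (df.to_numpy() < 0).any():
            raise FormatError(f"negative counts in {path}")
        adata = AnnData(X=sp.csr_matrix(df.to_numpy()),
                        obs=pd.DataFrame(index=df.index.astype(str)),
                        var=pd.DataFrame(index=df.columns.astype(str)))
    else:
        raise ValidationError(f"unknown format {fmt!r}")
    if adata.obs_names.duplicated().any() or adata.var_names.duplicated().any():
        raise FormatError("duplicate cell or gene identifiers")
    return adata


def write_matrix(adata: AnnData, outdir: str | Path) -> None:
    """Write counts as MatrixMarket triplet with barcode/feature sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(outdir / "matrix.mtx", sp.coo_matrix(adata.X), field="integer")
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", index=False, header=False)
    pd.Series(adata.var_names).to_csv(outdir / "features.tsv", index=False, header=False)


def _features_counts(adata: AnnData) -> tuple[np.ndarray, np.ndarray]:
    X = sp.csr_matrix(adata.X)
    features = X.getnnz(axis=1)
    counts = np.asarray(X.sum(axis=1)).ravel()
    return features, counts


def apply_qc(adata: AnnData, thresholds: QCThresholds | None = None
             ) -> tuple[AnnData, pd.DataFrame]:
    """Filter cells by feature count, total counts, and complexity.

    Returns the filtered matrix and a per-cell report listing, for removed
    cells, the first rule they failed (rules checked in the order
    min_features, max_features, min_counts, min_complexity).
    """
    thresholds = thresholds or QCThresholds()
    features, counts = _features_counts(adata)
    with np.errstate(divide="ignore", invalid="ignore"):
        if thresholds.complexity_mode == "log10_ratio":
            complexity = np.log10(features) / np.log10(counts)
        else:
            complexity = np.log2(features / counts)
    complexity = np.where((features > 0) & (counts > 1), complexity, -np.inf)

    reasons = np.array(["pass"] * adata.n_obs, dtype=object)
    reasons[complexity < thresholds.min_complexity] = "min_complexity"
    reasons[counts < thresholds.min_counts] = "min_counts"
    reasons[features > thresholds.max_features] = "max_features"
    reasons[features < thresholds.min_features] = "min_features"

    report = pd.DataFrame({
        "cell_id": adata.obs_names,
        "features": features,
        "counts": counts.astype(np.int64),
        "complexity": complexity,
        "qc_pass": reasons == "pass",
        "failed_rule": np.where(reasons == "pass", "", reasons),
    })
    keep = reasons == "pass"
    if not keep.any():
        raise ValidationError("QC removed all cells")
    return adata[keep].copy(), report


def normalize(adata: AnnData, scale_factor: float = 10_000.0,
              log_base: str = "natural") -> AnnData:
    """Library-size log-normalization into ``layers["lognorm"]``.

    normalized[c, g] = log(1 + scale_factor * counts[c, g] / total[c]) in
    the chosen base (``natural`` or ``log2``). Returns the same AnnData
    with the layer added.
    """
    if log_base not in ("natural", "log2"):
        raise ValidationError(f"unknown log_base {log_base!r}")
    X = sp.csr_matrix(adata.X, dtype=np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = adata.obs_names[totals == 0].tolist()
        raise ValidationError(f"zero-total cells cannot be normalized: {bad}")
    norm = X.multiply(scale_factor / totals[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    if log_base == "log2":
        norm.data /= np.log(2.0)
    adata.layers[LOGNORM_LAYER] = norm
    adata.uns["normalization"] = {"scale_factor": scale_factor, "log_base": log_base}
    return adata
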