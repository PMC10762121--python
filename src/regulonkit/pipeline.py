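"""End-to-end pipeline orchestration with a YAML config and run manifest.

Stages run in the order QC → normalization → coexpression network → binding
targets → regulons → activity → specificity → modules → relatedness →
differentiation score → evaluation, each writing its table under the output
directory; the manifest records parameters, the global seed, and a SHA-256
checksum per output so deterministic stages can be verified across reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import binding as _binding
from . import io_qc as _io_qc
from . import signatures as _signatures
from ._utils import ValidationError, derive_seed
from .model import RegulonNetworkModel


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run. Loadable from YAML."""

    matrix_path: str = ""
    matrix_format: str = "mtx_triplet"
    cells_path: str = ""
    tf_list_path: str = ""
    peaks_dir: str = ""
    gene_annotation_path: str = ""
    gold_path: str = ""
    early_markers_path: str = ""
    late_markers_path: str = ""
    outdir: str = "pipeline_out"

    qc: dict = field(default_factory=dict)            # QCThresholds fields
    scale_factor: float = 10_000.0
    log_base: str = "natural"
    method: str = "abs_spearman"
    n_runs: int = 1
    n_top_edges: int | None = None
    window_bp: int = 1000
    min_regulon_size: int = 5
    threshold_fraction: float = 0.05
    binarize_cutoff: float = 0.15
    n_modules: int | None = None
    relatedness_threshold: float = 0.0
    r_max: int = 1500
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, config: PipelineConfig, stage: str,
           index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# regulonkit stage={stage} seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    t0 = time.time()

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = round(time.time() - t0, 3)
        for p in paths:
            manifest["outputs"][str(p.relative_to(outdir))] = _checksum(p)

    def stage_fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- load + QC + normalize ------------------------------------------
    try:
        adata = _io_qc.read_matrix(config.matrix_path, fmt=config.matrix_format)
        cells = pd.read_csv(config.cells_path, sep="\t").set_index("cell_id")
        adata.obs = adata.obs.join(cells)
        adata, qc_report = _io_qc.apply_qc(adata, _io_qc.QCThresholds(**config.qc))
        adata = _io_qc.normalize(adata, scale_factor=config.scale_factor,
                                 log_base=config.log_base)
        qc_path = outdir / "qc_report.tsv"
        _write(qc_report, qc_path, config, "qc")
        record("qc", qc_path)
    except (OSError, ValidationError, KeyError) as exc:
        stage_fail("io_qc", exc)

    # --- binding targets -------------------------------------------------
    try:
        peaks_dir = Path(config.peaks_dir)
        if not peaks_dir.is_dir():
            raise ValidationError(f"peaks_dir {peaks_dir} does not exist")
        peaks = {p.stem: _binding.read_bed(p) for p in sorted(peaks_dir.glob("*.bed"))}
        annotation = _binding.read_gene_annotation(config.gene_annotation_path)
        tf_list = [t for t in Path(config.tf_list_path).read_text().split() if t]
    except (OSError, ValidationError) as exc:
        stage_fail("binding_targets", exc)

    # --- model fit: coexpression → regulons → activity → rss → modules --
    model = RegulonNetworkModel(adata, tf_list, peaks, annotation)
    results = model.fit(
        method=config.method, n_runs=config.n_runs,
        n_top_edges=config.n_top_edges, window_bp=config.window_bp,
        min_regulon_size=config.min_regulon_size,
        threshold_fraction=config.threshold_fraction,
        binarize_cutoff=config.binarize_cutoff, n_modules=config.n_modules,
        relatedness_threshold=config.relatedness_threshold,
        seed=derive_seed(config.seed, "fit"))

    paths = []
    for name, df, index in [
        ("edges_top.tsv", results.top_edges, False),
        ("target_assignments.tsv", results.target_assignments, False),
        ("regulons.tsv", results.regulons.to_frame(), False),
        ("activity.tsv", results.activity.ras, True),
        ("activity_binarized.tsv", results.activity.binarized, True),
        ("rss.tsv", results.rss, True),
        ("summary.tsv", results.summary(), True),
    ]:
        p = outdir / name
        _write(df, p, config, name.split(".")[0], index=index)
        paths.append(p)
    if results.modules is not None:
        p = outdir / "modules.tsv"
        _write(results.modules.rename("module").to_frame(), p, config,
               "modules", index=True)
        paths.append(p)
        p = outdir / "module_activity.tsv"
        _write(results.module_activity, p, config, "module_activity", index=True)
        paths.append(p)
    if results.relatedness_edges is not None:
        p = outdir / "cluster_relatedness.tsv"
        _write(results.relatedness_edges, p, config, "relatedness")
        paths.append(p)
    record("network", *paths)

    # --- differentiation score (optional) --------------------------------
    if config.early_markers_path and config.late_markers_path:
        try:
            early = set(Path(config.early_markers_path).read_text().split())
            late = set(Path(config.late_markers_path).read_text().split())
            gsc_early = _signatures.signature_score(adata, early, r_max=config.r_max)
            gsc_late = _signatures.signature_score(adata, late, r_max=config.r_max)
            diff = _signatures.differentiation_score(gsc_early, gsc_late)
            table = pd.DataFrame({"gsc_early": gsc_early, "gsc_late": gsc_late,
                                  "differentiation_score": diff})
            p = outdir / "differentiation_score.tsv"
            _write(table, p, config, "diffscore", index=True)
            record("diffscore", p)
        except (OSError, ValidationError) as exc:
            stage_fail("signatures", exc)

    # --- evaluation (optional) -------------------------------------------
    if config.gold_path:
        try:
            gold = pd.read_csv(config.gold_path, sep="\t")
            res_bin = results.evaluate(gold, mode="binary")
            res_rank = results.evaluate(gold, mode="ranked")
            table = pd.DataFrame(
                {"mode": ["binary", "ranked"],
                 "auc_roc": [res_bin.auc_roc, res_rank.auc_roc],
                 "auc_pr": [res_bin.auc_pr, res_rank.auc_pr]})
            p = outdir / "evaluation.tsv"
            _write(table, p, config, "evaluation")
            record("evaluation", p)
        except (OSError, ValidationError) as exc:
            stage_fail("evaluation", exc)

    manifest["elapsed_s"] = round(time.time() - t0, 3)
    manifest["params"] = dataclasses.asdict(config)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
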