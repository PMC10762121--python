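"""Synthetic single-cell datasets with planted regulatory structure.

Emulates the statistical shape of a droplet scRNA-seq study of a
differentiating tissue combined with TF-binding assays: clustered
negative-binomial counts with dropout, transcription factors whose target
genes are co-upregulated in the TF's home cluster, binding peaks placed
near target transcription start sites at a controlled true-positive rate,
and stage-marker genes shifted between an early and a late timepoint.
Every downstream stage of the package is testable against the planted
ground truth without any external download.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.io import mmwrite

from ._utils import ValidationError, derive_seed
from .regulons import RegulonSet

PEAK_WIDTH = 200
TSS_SPACING = 10_000
GENES_PER_CHROM = 100


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults are the package's reference conditions: ~2,000 cells in six
    clusters, 40 TFs with 20 targets each, four-fold cluster effects on a
    moderately overdispersed negative-binomial baseline with 20% dropout,
    and binding peaks recovering true targets at 80% sensitivity with a 5%
    false-positive rate.
    """

    n_cells: int = 2000
    n_genes: int = 1000
    n_clusters: int = 6
    n_tfs: int = 40
    targets_per_tf: int = 20
    effect_size: float = 4.0
    nb_dispersion: float = 2.0
    dropout_rate: float = 0.2
    binding_tpr: float = 0.8
    binding_fpr: float = 0.05
    stage_marker_count: int = 50
    background_per_cluster: int = 25
    hard_negative_fraction: float = 0.5
    fraction_late: float = 0.5
    seed: int = 0

    @classmethod
    def scaled(cls, n_cells: int = 2000, n_genes: int = 1000,
               n_clusters: int = 6, n_tfs: int = 40, seed: int = 0,
               **overrides) -> "SimulationConfig":
        """A config whose per-gene-pool counts shrink with the panel size.

        Keeps regulon targets, background programs and stage markers in
        proportion so that small panels remain generable; explicit keyword
        overrides win.
        """
        pool = n_genes - n_tfs
        targets_per_tf = max(1, min(20, pool // (5 * max(n_tfs, 1))))
        background = max(2, min(25, pool // (10 * max(n_clusters, 1))))
        remaining = pool - n_tfs * targets_per_tf - n_clusters * background
        stage = max(2, min(50, remaining // 4))
        params = dict(n_cells=n_cells, n_genes=n_genes, n_clusters=n_clusters,
                      n_tfs=n_tfs, targets_per_tf=targets_per_tf,
                      background_per_cluster=background,
                      stage_marker_count=stage, seed=seed)
        params.update(overrides)
        return cls(**params)

    def validate(self) -> None:
        for name in ("n_cells", "n_genes", "n_clusters", "n_tfs",
                     "targets_per_tf", "stage_marker_count"):
            if int(getattr(self, name)) < 1:
                raise ValidationError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("dropout_rate", "binding_tpr", "binding_fpr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.effect_size <= 1.0:
            raise ValidationError(f"effect_size must be > 1, got {self.effect_size}")
        if self.nb_dispersion <= 0:
            raise ValidationError(f"nb_dispersion must be > 0, got {self.nb_dispersion}")
        if self.n_tfs > self.n_genes:
            raise ValidationError("n_tfs must not exceed n_genes")
        if self.targets_per_tf > self.n_genes - self.n_tfs:
            raise ValidationError("targets_per_tf must not exceed n_genes - n_tfs")
        if not 0.0 < self.fraction_late < 1.0:
            raise ValidationError(f"fraction_late must be in (0, 1), got {self.fraction_late}")
        if self.background_per_cluster < 0:
            raise ValidationError("background_per_cluster must be >= 0")
        if not 0.0 <= self.hard_negative_fraction <= 1.0:
            raise ValidationError("hard_negative_fraction must be in [0, 1]")


@dataclass
class SyntheticDataset:
    """A generated dataset plus all planted ground truth."""

    adata: AnnData
    gene_annotation: pd.DataFrame
    peaks: dict[str, pd.DataFrame]
    gold_edges: pd.DataFrame
    planted_regulons: RegulonSet
    planted_modules: dict[str, str]
    stage_markers: tuple[set[str], set[str]]  # (early, late)
    config: SimulationConfig = field(repr=False)

    @property
    def tf_ids(self) -> list[str]:
        return list(self.planted_regulons.tfs)


def _gene_ids(config: SimulationConfig) -> list[str]:
    tf_ids = [f"TF{i + 1:04d}" for i in range(config.n_tfs)]
    other = [f"G{i + 1:05d}" for i in range(config.n_genes - config.n_tfs)]
    return tf_ids + other


def generate_two_stage_labels(n_cells: int, fraction_late: float, seed: int = 0) -> pd.Series:
    """Assign each cell an early/late timepoint label.

    The number of late cells is round(fraction_late * n_cells), so realised
    proportions are always within one cell of the request; which cells are
    late is a seeded draw.
    """
    if not 0.0 < fraction_late < 1.0:
        raise ValidationError(f"fraction_late must be in (0, 1), got {fraction_late}")
    rng = np.random.default_rng(derive_seed(seed, "stage_labels"))
    n_late = int(round(fraction_late * n_cells))
    labels = np.array(["early"] * n_cells, dtype=object)
    labels[rng.choice(n_cells, size=n_late, replace=False)] = "late"
    return pd.Series(labels, index=[f"cell{i + 1:05d}" for i in range(n_cells)],
                     name="timepoint")


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset from a validated config.

    Cells are partitioned into contiguous, near-equal clusters; each TF has
    a home cluster (round-robin) where it and its targets are upregulated
    by ``effect_size``; counts are negative binomial with independent
    Bernoulli dropout; each gene receives a TSS on a synthetic genome with
    ±3 kb windows guaranteed disjoint; peaks land in the ±1 kb window of
    true targets with probability ``binding_tpr`` and of sampled non-targets
    with probability ``binding_fpr``. Fully deterministic given the seed.
    """
    config.validate()
    cfg = config
    gene_ids = _gene_ids(cfg)
    tf_ids = gene_ids[: cfg.n_tfs]
    non_tf = gene_ids[cfg.n_tfs:]
    cell_ids = [f"cell{i + 1:05d}" for i in range(cfg.n_cells)]

    # cluster assignment: contiguous near-equal blocks
    clusters = np.floor(np.arange(cfg.n_cells) * cfg.n_clusters / cfg.n_cells).astype(int)

    # per-gene baseline means
    rng_base = np.random.default_rng(derive_seed(cfg.seed, "baseline"))
    base_mean = rng_base.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)

    # planted regulons: each TF samples targets from the non-TF pool
    rng_net = np.random.default_rng(derive_seed(cfg.seed, "network"))
    regulon_targets: dict[str, list[str]] = {}
    home_cluster: dict[str, int] = {}
    for i, tf in enumerate(tf_ids):
        home_cluster[tf] = i % cfg.n_clusters
        picks = rng_net.choice(len(non_tf), size=cfg.targets_per_tf, replace=False)
        regulon_targets[tf] = [non_tf[j] for j in sorted(picks)]

    # background cluster programs: genes upregulated in one cluster but not
    # bound by any assayed TF — the co-varying transcriptional context that
    # confounds coexpression-only network inference
    planted = {g for ts in regulon_targets.values() for g in ts}
    rng_bg = np.random.default_rng(derive_seed(cfg.seed, "background"))
    bg_pool = [g for g in non_tf if g not in planted]
    n_bg = cfg.background_per_cluster * cfg.n_clusters
    if n_bg > len(bg_pool):
        raise ValidationError(
            "background_per_cluster too large for the number of unplanted genes")
    bg_idx = rng_bg.choice(len(bg_pool), size=n_bg, replace=False)
    background: dict[int, list[str]] = {
        c: [bg_pool[j] for j in sorted(bg_idx[c * cfg.background_per_cluster:
                                              (c + 1) * cfg.background_per_cluster])]
        for c in range(cfg.n_clusters)}
    bg_genes = {g for gs in background.values() for g in gs}

    # stage structure
    timepoint = generate_two_stage_labels(cfg.n_cells, cfg.fraction_late, cfg.seed)
    free = [g for g in non_tf if g not in planted and g not in bg_genes]
    rng_stage = np.random.default_rng(derive_seed(cfg.seed, "stage_markers"))
    n_mark = cfg.stage_marker_count
    if 2 * n_mark > len(free):
        raise ValidationError(
            "stage_marker_count too large for the number of unplanted genes")
    marker_idx = rng_stage.choice(len(free), size=2 * n_mark, replace=False)
    early_markers = {free[j] for j in marker_idx[:n_mark]}
    late_markers = {free[j] for j in marker_idx[n_mark:]}

    # mean matrix: baseline, times effect in (home cluster x regulon genes),
    # stage markers shifted in late cells
    gene_pos = {g: j for j, g in enumerate(gene_ids)}
    mean = np.tile(base_mean, (cfg.n_cells, 1))
    for tf in tf_ids:
        cols = [gene_pos[tf]] + [gene_pos[g] for g in regulon_targets[tf]]
        rows = clusters == home_cluster[tf]
        mean[np.ix_(rows, cols)] *= cfg.effect_size
    for c, genes_c in background.items():
        if genes_c:
            mean[np.ix_(clusters == c, [gene_pos[g] for g in genes_c])] *= cfg.effect_size
    late_rows = (timepoint == "late").to_numpy()
    late_cols = [gene_pos[g] for g in sorted(late_markers)]
    early_cols = [gene_pos[g] for g in sorted(early_markers)]
    mean[np.ix_(late_rows, late_cols)] *= cfg.effect_size
    mean[np.ix_(late_rows, early_cols)] /= cfg.effect_size

    # negative-binomial sampling: size theta, p = theta / (theta + mean)
    rng_counts = np.random.default_rng(derive_seed(cfg.seed, "counts"))
    theta = cfg.nb_dispersion
    counts = rng_counts.negative_binomial(theta, theta / (theta + mean)).astype(np.int64)
    if cfg.dropout_rate > 0:
        keep = rng_counts.random(counts.shape) >= cfg.dropout_rate
        counts *= keep

    adata = AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame(
            {"cluster": pd.Categorical([f"C{c}" for c in clusters]),
             "timepoint": pd.Categorical(timepoint.to_numpy())},
            index=cell_ids),
        var=pd.DataFrame({"is_tf": [g in set(tf_ids) for g in gene_ids]},
                         index=gene_ids),
    )

    # synthetic genome: GENES_PER_CHROM genes per chromosome, TSSs spaced
    # TSS_SPACING apart, alternating strand; +-3 kb windows never overlap
    idx = np.arange(cfg.n_genes)
    gene_annotation = pd.DataFrame({
        "gene_id": gene_ids,
        "chrom": [f"chr{i // GENES_PER_CHROM + 1}" for i in idx],
        "tss": (idx % GENES_PER_CHROM) * TSS_SPACING + TSS_SPACING // 2,
        "strand": np.where(idx % 2 == 0, "+", "-"),
    })
    ann = gene_annotation.set_index("gene_id")

    # peaks: true targets at binding_tpr, sampled decoys at binding_fpr
    rng_peaks = np.random.default_rng(derive_seed(cfg.seed, "peaks"))
    window = 1000
    peaks: dict[str, pd.DataFrame] = {}
    for tf in tf_ids:
        rows = []
        truth = set(regulon_targets[tf])
        for g in regulon_targets[tf]:
            if rng_peaks.random() < cfg.binding_tpr:
                rows.append(_peak_near(ann.loc[g], window, rng_peaks))
        decoys = [g for g in gene_ids if g not in truth and g != tf]
        hit = rng_peaks.random(len(decoys)) < cfg.binding_fpr
        for g, h in zip(decoys, hit):
            if h:
                rows.append(_peak_near(ann.loc[g], window, rng_peaks))
        peaks[tf] = pd.DataFrame(rows, columns=["chrom", "start", "end"]).astype(
            {"start": np.int64, "end": np.int64}) if rows else pd.DataFrame(
            columns=["chrom", "start", "end"])

    # gold standard: positives = planted edges; negatives are unplanted
    # TF-gene pairs, drawn partly from the TF's home-cluster program
    # (co-cluster TFs' targets and background genes — coexpressed but not
    # bound, the hard negatives a documented-target evaluation contains)
    # and partly uniformly from the remaining unplanted genes
    rng_gold = np.random.default_rng(derive_seed(cfg.seed, "gold"))
    cluster_program: dict[int, set[str]] = {c: set(background[c])
                                            for c in range(cfg.n_clusters)}
    for tf in tf_ids:
        cluster_program[home_cluster[tf]].update(regulon_targets[tf])
    records = []
    for tf in tf_ids:
        truth = set(regulon_targets[tf])
        for g in regulon_targets[tf]:
            records.append((tf, g, 1))
        hard_pool = sorted(cluster_program[home_cluster[tf]] - truth)
        n_hard = min(int(round(cfg.hard_negative_fraction * cfg.targets_per_tf)),
                     len(hard_pool))
        negs = [hard_pool[j] for j in
                rng_gold.choice(len(hard_pool), size=n_hard, replace=False)]
        easy_pool = [g for g in non_tf if g not in truth and g not in set(negs)]
        n_easy = cfg.targets_per_tf - n_hard
        negs += [easy_pool[j] for j in
                 rng_gold.choice(len(easy_pool), size=n_easy, replace=False)]
        for g in sorted(set(negs)):
            records.append((tf, g, 0))
    gold_edges = pd.DataFrame(records, columns=["tf", "target", "label"])

    planted_regulons = RegulonSet(
        {tf: pd.DataFrame({"target": regulon_targets[tf]}) for tf in tf_ids})
    planted_modules = {tf: f"M{home_cluster[tf] + 1}" for tf in tf_ids}

    return SyntheticDataset(
        adata=adata,
        gene_annotation=gene_annotation,
        peaks=peaks,
        gold_edges=gold_edges,
        planted_regulons=planted_regulons,
        planted_modules=planted_modules,
        stage_markers=(early_markers, late_markers),
        config=dataclasses.replace(cfg),
    )


def _peak_near(gene_row: pd.Series, window: int, rng: np.random.Generator) -> tuple:
    """A fixed-width peak whose centre is uniform in the ±window TSS span."""
    center = int(gene_row["tss"]) + int(rng.integers(-window, window + 1))
    start0 = max(center - PEAK_WIDTH // 2, 0)  # BED 0-based half-open
    return (gene_row["chrom"], start0, start0 + PEAK_WIDTH)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset to plain-text standard formats.

    MatrixMarket triplet + barcodes/features sidecars, cell-metadata TSV,
    gene-annotation TSV, BED6 per TF, gold-edge TSV, stage-marker gene
    lists, and a regulon table for the planted truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["matrix"] = outdir / "matrix.mtx"
    mmwrite(paths["matrix"], sp.coo_matrix(dataset.adata.X), field="integer")
    paths["barcodes"] = outdir / "barcodes.tsv"
    paths["features"] = outdir / "features.tsv"
    pd.Series(dataset.adata.obs_names).to_csv(paths["barcodes"], index=False, header=False)
    pd.Series(dataset.adata.var_names).to_csv(paths["features"], index=False, header=False)

    paths["cells"] = outdir / "cells.tsv"
    obs = dataset.adata.obs.reset_index(names="cell_id")
    obs.to_csv(paths["cells"], sep="\t", index=False)

    paths["genes"] = outdir / "gene_annotation.tsv"
    dataset.gene_annotation.to_csv(paths["genes"], sep="\t", index=False)

    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for tf, df in dataset.peaks.items():
        p = peak_dir / f"{tf}.bed"
        bed = df.copy()
        bed["name"] = tf
        bed["score"] = 0
        bed["strand"] = "."
        bed.to_csv(p, sep="\t", index=False, header=False)
    paths["peaks_dir"] = peak_dir

    paths["gold"] = outdir / "gold_edges.tsv"
    dataset.gold_edges.to_csv(paths["gold"], sep="\t", index=False)

    paths["tf_list"] = outdir / "tf_list.txt"
    paths["tf_list"].write_text("\n".join(dataset.tf_ids) + "\n")

    early, late = dataset.stage_markers
    paths["early_markers"] = outdir / "stage_markers_early.txt"
    paths["late_markers"] = outdir / "stage_markers_late.txt"
    paths["early_markers"].write_text("\n".join(sorted(early)) + "\n")
    paths["late_markers"].write_text("\n".join(sorted(late)) + "\n")

    paths["regulons"] = outdir / "planted_regulons.tsv"
    dataset.planted_regulons.to_frame().to_csv(paths["regulons"], sep="\t", index=False)
    return paths
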