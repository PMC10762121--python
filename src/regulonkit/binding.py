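"""Peak-to-gene assignment: high-confidence direct targets from binding.

Peaks arrive as BED (0-based half-open); gene TSSs are 1-based (GFF
convention). Conversion happens at read time; all internal arithmetic is
1-based inclusive. A gene is a high-confidence target of a TF iff some
peak overlaps the ±window_bp span around the gene's TSS — any shared base
counts, so the rule is invariant to splitting a peak into abutting halves.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import ValidationError

TARGET_COLUMNS = ["tf", "gene_id", "category", "distance_to_tss"]


def read_bed(path: str | Path, tf_id: str | None = None) -> pd.DataFrame:
    """Read peak intervals from a BED file (first three columns used)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValidationError(f"{path}: BED needs at least 3 columns")
    peaks = df.iloc[:, :3].copy()
    peaks.columns = ["chrom", "start", "end"]
    peaks = peaks.astype({"start": np.int64, "end": np.int64})
    if (peaks["start"] >= peaks["end"]).any():
        raise ValidationError(f"{path}: intervals must satisfy start < end")
    peaks.attrs["tf"] = tf_id or path.stem
    return peaks


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Gene annotation TSV with columns gene_id, chrom, tss, strand."""
    ann = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss", "strand"}
    if not required.issubset(ann.columns):
        raise ValidationError(f"annotation needs columns {sorted(required)}")
    if ann["gene_id"].duplicated().any():
        raise ValidationError("duplicate gene_id in annotation")
    return ann


def assign_targets(peaks: dict[str, pd.DataFrame] | pd.DataFrame,
                   annotation: pd.DataFrame, window_bp: int = 1000,
                   promoter_bp: int = 3000) -> pd.DataFrame:
    """Assign genes to TFs by peak proximity to the TSS.

    Returns one row per (tf, gene) pair with a peak inside the ±promoter_bp
    span, categorised ``high_confidence`` when some peak overlaps the
    ±window_bp span, else ``promoter_3kb``. Distance is peak midpoint minus
    TSS, sign flipped on − strand so negative always means upstream in gene
    orientation; the closest peak's distance is reported. The ±window is
    symmetric, so strand affects only the distance sign.
    """
    if annotation.empty:
        raise ValidationError("empty gene annotation")
    if isinstance(peaks, pd.DataFrame):
        peaks = {peaks.attrs.get("tf", "TF"): peaks}

    known = set(annotation["chrom"])
    rows = []
    by_chrom = {c: g.sort_values("tss") for c, g in annotation.groupby("chrom")}
    for tf, pk in peaks.items():
        if pk.empty:
            continue
        bad = set(pk["chrom"]) - known
        if bad:
            warnings.warn(f"{tf}: skipping peaks on unknown chromosomes {sorted(bad)}",
                          stacklevel=2)
        for chrom, sub in pk.groupby("chrom"):
            if chrom not in by_chrom:
                continue
            genes = by_chrom[chrom]
            tss = genes["tss"].to_numpy()
            # BED half-open [s, e) -> 1-based inclusive [s+1, e]
            p_lo = sub["start"].to_numpy() + 1
            p_hi = sub["end"].to_numpy()
            mid = (p_lo - 1 + p_hi) / 2.0  # continuous-coordinate midpoint
            for lo, hi, m in zip(p_lo, p_hi, mid):
                near = np.flatnonzero((lo <= tss + promoter_bp) & (hi >= tss - promoter_bp))
                for gi in near:
                    g = genes.iloc[gi]
                    hc = (lo <= g["tss"] + window_bp) and (hi >= g["tss"] - window_bp)
                    dist = m - g["tss"]
                    if g["strand"] == "-":
                        dist = -dist
                    rows.append((tf, g["gene_id"],
                                 "high_confidence" if hc else "promoter_3kb",
                                 float(dist)))
    out = pd.DataFrame(rows, columns=TARGET_COLUMNS)
    if out.empty:
        return out
    # one row per (tf, gene): best category, closest peak distance
    rank = out["category"].map({"high_confidence": 0, "promoter_3kb": 1})
    out = (out.assign(_rank=rank, _absd=out["distance_to_tss"].abs())
              .sort_values(["tf", "gene_id", "_rank", "_absd"])
              .drop_duplicates(["tf", "gene_id"], keep="first")
              .drop(columns=["_rank", "_absd"])
              .reset_index(drop=True))
    return out


def annotate_promoters(peaks: pd.DataFrame, annotation: pd.DataFrame,
                       promoter_bp: int = 3000) -> tuple[pd.Series, pd.Series]:
    """Label each peak promoter/distal by overlap with any ±promoter_bp TSS span.

    Returns the per-peak labels and the category counts.
    """
    if annotation.empty:
        raise ValidationError("empty gene annotation")
    labels = []
    by_chrom = {c: g["tss"].to_numpy() for c, g in annotation.groupby("chrom")}
    for _, pk in peaks.iterrows():
        tss = by_chrom.get(pk["chrom"])
        lo, hi = pk["start"] + 1, pk["end"]
        is_prom = tss is not None and bool(
            np.any((lo <= tss + promoter_bp) & (hi >= tss - promoter_bp)))
        labels.append("promoter" if is_prom else "distal")
    labels = pd.Series(labels, index=peaks.index, name="category")
    return labels, labels.value_counts()


def genome_coverage(peak_sets: dict[str, pd.DataFrame],
                    genome_sizes: dict[str, int]) -> dict:
    """Fraction of the genome covered by any peak, and per-base TF-count histogram.

    Uses an event-sweep over interval endpoints per chromosome; peaks
    running past a chromosome end are clamped with a warning. The
    histogram maps (number of distinct TFs covering a base) -> base count,
    including 0 for uncovered bases.
    """
    genome_len = sum(genome_sizes.values())
    if genome_len <= 0:
        raise ValidationError("genome sizes must be positive")
    hist: dict[int, int] = {}
    covered = 0
    for chrom, size in genome_sizes.items():
        events: dict[int, int] = {}
        for tf, pk in peak_sets.items():
            sub = pk[pk["chrom"] == chrom]
            if sub.empty:
                continue
            # merge one TF's intervals so a base counts each TF once
            ivs = sorted(zip(sub["start"], sub["end"]))
            merged = []
            for s, e in ivs:
                if e > size or s < 0:
                    warnings.warn(f"{tf}: clamping peak [{s},{e}) to chromosome "
                                  f"{chrom} of length {size}", stacklevel=2)
                    s, e = max(s, 0), min(e, size)
                if s >= e:
                    continue
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            for s, e in merged:
                events[s] = events.get(s, 0) + 1
                events[e] = events.get(e, 0) - 1
        depth, prev = 0, 0
        for pos in sorted(events):
            span = pos - prev
            if span > 0:
                hist[depth] = hist.get(depth, 0) + span
                if depth > 0:
                    covered += span
            depth += events[pos]
            prev = pos
        hist[0] = hist.get(0, 0) + (size - prev)
    return {"covered_fraction": covered / genome_len,
            "tf_count_histogram": dict(sorted(hist.items()))}
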