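"""Regulon construction: coexpression targets ∩ binding targets.

A regulon is a transcription factor together with the set of genes that
are both coexpressed with it (an edge in the top-ranked coexpression
network) and directly bound by it (a high-confidence peak near the gene's
TSS). The intersection is what turns a noisy coexpression network into a
direct-target network.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from ._utils import ValidationError


class RegulonSet:
    """Per-TF target tables with provenance columns.

    Each TF maps to a DataFrame with at least a ``target`` column; optional
    columns carry provenance (coexpression ``importance``, binding
    ``distance_to_tss``).
    """

    def __init__(self, regulons: dict[str, pd.DataFrame]):
        self._regulons = {tf: df.reset_index(drop=True) for tf, df in regulons.items()}

    @property
    def tfs(self) -> list[str]:
        return list(self._regulons)

    def targets(self, tf: str) -> set[str]:
        return set(self._regulons[tf]["target"])

    def table(self, tf: str) -> pd.DataFrame:
        return self._regulons[tf]

    def sizes(self) -> pd.Series:
        return pd.Series({tf: len(df) for tf, df in self._regulons.items()},
                         name="n_targets")

    def __len__(self) -> int:
        return len(self._regulons)

    def __contains__(self, tf: str) -> bool:
        return tf in self._regulons

    def __iter__(self):
        return iter(self._regulons)

    def as_dict(self) -> dict[str, set[str]]:
        return {tf: self.targets(tf) for tf in self.tfs}

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for tf, df in self._regulons.items():
            d = df.copy()
            d.insert(0, "tf", tf)
            frames.append(d)
        if not frames:
            return pd.DataFrame(columns=["tf", "target"])
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RegulonSet":
        return cls({tf: df.drop(columns="tf") for tf, df in frame.groupby("tf", sort=True)})

    def write_gmt(self, path: str | Path) -> None:
        """GMT gene-set export: one regulon per line (name, description, genes)."""
        lines = []
        for tf in sorted(self._regulons):
            genes = sorted(self.targets(tf))
            lines.append("\t".join([tf, f"regulon({tf})"] + genes))
        Path(path).write_text("\n".join(lines) + "\n")


def build_regulons(top_edges: pd.DataFrame, targets: pd.DataFrame) -> RegulonSet:
    """Intersect coexpression edges with high-confidence binding targets.

    ``top_edges``: columns (tf, target, importance). ``targets``: the
    assignment table from :mod:`regulonkit.binding` with columns
    (tf, gene_id, category, distance_to_tss). A gene enters regulon(tf) iff
    (tf, gene) is a coexpression edge AND a high-confidence binding target.
    TFs whose intersection is empty are kept as empty regulons so that
    filtering remains a separate, reportable step.
    """
    if top_edges.empty or targets.empty:
        raise ValidationError("build_regulons requires non-empty edges and targets")
    hc = targets[targets["category"] == "high_confidence"]
    binding = hc.set_index(["tf", "gene_id"])["distance_to_tss"]
    regulons: dict[str, pd.DataFrame] = {}
    for tf, df in top_edges.groupby("tf", sort=True):
        rows = []
        for _, rec in df.iterrows():
            key = (tf, rec["target"])
            if key in binding.index:
                rows.append((rec["target"], rec["importance"], binding.loc[key]))
        regulons[tf] = pd.DataFrame(
            rows, columns=["target", "importance", "distance_to_tss"]
        ).sort_values("target").reset_index(drop=True)
    return RegulonSet(regulons)


def filter_regulons(regulons: RegulonSet, min_size: int = 5,
                    exclude: set[str] | None = None) -> tuple[RegulonSet, pd.DataFrame]:
    """Drop regulons with fewer than ``min_size`` targets.

    ``exclude`` is an optional user-supplied TF blacklist (hook for quality
    filters beyond size). Returns the retained set and a report of dropped
    TFs with the reason.
    """
    exclude = exclude or set()
    kept: dict[str, pd.DataFrame] = {}
    dropped = []
    for tf in regulons.tfs:
        n = len(regulons.table(tf))
        if tf in exclude:
            dropped.append((tf, n, "excluded"))
        elif n < min_size:
            dropped.append((tf, n, "below_min_size"))
        else:
            kept[tf] = regulons.table(tf)
    report = pd.DataFrame(dropped, columns=["tf", "n_targets", "reason"])
    if not kept:
        raise ValidationError("filter_regulons removed every regulon")
    if not report.empty:
        warnings.warn(f"filter_regulons dropped {len(report)} regulons", stacklevel=2)
    return RegulonSet(kept), report
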