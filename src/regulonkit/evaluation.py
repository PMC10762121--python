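"""Evaluate predicted networks against a gold standard with ROC/PR curves.

Gold-standard pairs absent from the prediction score 0 rather than being
dropped — a documented target the method never predicts is a miss, and
recall must reflect it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc, precision_recall_curve, roc_curve

from ._utils import ValidationError
from .regulons import RegulonSet


@dataclass
class EvaluationResult:
    roc_points: pd.DataFrame  # columns fpr, tpr
    pr_points: pd.DataFrame   # columns recall, precision
    auc_roc: float
    auc_pr: float


def score_predictions(predicted: pd.DataFrame | RegulonSet, gold: pd.DataFrame,
                      mode: str = "ranked") -> pd.DataFrame:
    """Attach a prediction score to every gold-standard pair.

    ``ranked`` mode takes the coexpression importance of each (tf, target)
    pair, 0 when absent; ``binary`` mode scores 1 iff the pair is a regulon
    member. Returns columns (tf, target, label, score).
    """
    if gold.empty:
        raise ValidationError("empty gold standard")
    if gold.duplicated(["tf", "target"]).any():
        raise ValidationError("duplicate pairs in gold standard")
    out = gold[["tf", "target", "label"]].copy()
    if mode == "ranked":
        if isinstance(predicted, RegulonSet):
            raise ValidationError("ranked mode needs an edge list with importances")
        lookup = predicted.set_index(["tf", "target"])["importance"]
        keys = pd.MultiIndex.from_frame(out[["tf", "target"]])
        out["score"] = lookup.reindex(keys).fillna(0.0).to_numpy()
    elif mode == "binary":
        if isinstance(predicted, RegulonSet):
            members = {(tf, g) for tf in predicted.tfs for g in predicted.targets(tf)}
        else:
            members = set(zip(predicted["tf"], predicted["target"]))
        out["score"] = [1.0 if pair in members else 0.0
                        for pair in zip(out["tf"], out["target"])]
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return out


def roc_pr(scored: pd.DataFrame) -> EvaluationResult:
    """ROC and precision–recall curves with trapezoidal AUCs.

    The threshold sweep groups tied scores into single steps, which makes
    the ROC AUC equal the Mann–Whitney pair-ordering statistic with ties
    counted one half.
    """
    labels = scored["label"].to_numpy()
    scores = scored["score"].to_numpy(dtype=float)
    if labels.min() == labels.max():
        raise ValidationError("both classes must be present")
    fpr, tpr, _ = roc_curve(labels, scores)
    precision, recall, _ = precision_recall_curve(labels, scores)
    # integrate along the threshold path (recall non-decreasing after the
    # flip); duplicate-recall points form zero-width steps
    auc_pr = float(np.trapezoid(np.asarray(precision)[::-1],
                                np.asarray(recall)[::-1]))
    return EvaluationResult(
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        pr_points=pd.DataFrame({"recall": recall, "precision": precision}),
        auc_roc=float(auc(fpr, tpr)),
        auc_pr=auc_pr,
    )
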