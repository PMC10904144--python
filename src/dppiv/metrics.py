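"""Binary-classification evaluation: confusion counts, ACC/Sn/Sp/MCC and AUC.

The four threshold metrics are the standard formulas

    ACC = (TP + TN) / (TP + TN + FP + FN)
    Sn  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TN+FN)(TP+FN)(TN+FP))

and AUC is the rank-based (Mann–Whitney) statistic with midrank tie
handling.  A metric whose denominator is zero is reported as *undefined*
with a reason rather than silently coerced to 0 or NaN.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["ConfusionCounts", "confusion", "compute_metrics", "auc", "evaluate_scores"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts of the 2x2 classification table."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(labels, calls) -> ConfusionCounts:
    """Count the 2x2 table for binary labels and binary calls."""
    labels = np.asarray(labels).astype(int)
    calls = np.asarray(calls).astype(int)
    if labels.shape != calls.shape:
        raise ValueError(f"labels ({labels.shape}) and calls ({calls.shape}) differ in length")
    for name, v in (("labels", labels), ("calls", calls)):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"{name} must be binary 0/1")
    return ConfusionCounts(
        TP=int(np.sum((labels == 1) & (calls == 1))),
        TN=int(np.sum((labels == 0) & (calls == 0))),
        FP=int(np.sum((labels == 0) & (calls == 1))),
        FN=int(np.sum((labels == 1) & (calls == 0))),
    )


def compute_metrics(c: ConfusionCounts) -> dict:
    """ACC, Sn, Sp and MCC from a confusion table.

    Returns a dict with the four metric values (floats) plus an
    ``"undefined"`` sub-dict mapping any metric with a zero denominator to
    the reason it is undefined; undefined metrics hold ``None``.
    """
    undefined: dict[str, str] = {}
    out: dict = {"undefined": undefined}

    if c.total > 0:
        out["ACC"] = (c.TP + c.TN) / c.total
    else:
        out["ACC"] = None
        undefined["ACC"] = "no evaluated records"
    if c.TP + c.FN > 0:
        out["Sn"] = c.TP / (c.TP + c.FN)
    else:
        out["Sn"] = None
        undefined["Sn"] = "no positive labels (TP+FN = 0)"
    if c.TN + c.FP > 0:
        out["Sp"] = c.TN / (c.TN + c.FP)
    else:
        out["Sp"] = None
        undefined["Sp"] = "no negative labels (TN+FP = 0)"
    denom = (
        (c.TP + c.FP) * (c.TN + c.FN) * (c.TP + c.FN) * (c.TN + c.FP)
    )
    if denom > 0:
        out["MCC"] = (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom)
    else:
        out["MCC"] = None
        undefined["MCC"] = "a marginal of the confusion table is zero"
    if undefined:
        logger.warning("undefined metrics: %s", undefined)
    return out


def auc(labels, scores) -> float:
    """Rank-based (Mann–Whitney) area under the ROC curve, midrank ties."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same length")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes to be present")
    return float(roc_auc_score(labels, scores))


def evaluate_scores(labels, scores, threshold: float = 0.5) -> dict:
    """All five metrics plus the confusion table for probability scores."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=np.float64)
    calls = (scores >= threshold).astype(int)
    c = confusion(labels, calls)
    out = compute_metrics(c)
    out["AUC"] = auc(labels, scores) if len(np.unique(labels)) == 2 else None
    if out["AUC"] is None:
        out["undefined"]["AUC"] = "single-class labels"
    out["confusion"] = {"TP": c.TP, "TN": c.TN, "FP": c.FP, "FN": c.FN}
    out["threshold"] = threshold
    return out
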