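"""Binary-classification metrics: confusion counts, ACC/SEN/SPE/F1, rank AUC.

ACC = (TP+TN)/(TP+TN+FP+FN), SEN = TP/(TP+FN), SPE = TN/(TN+FP),
F1 = 2*Precision*Recall/(Precision+Recall) with Precision = TP/(TP+FP).
Metrics with a zero denominator are reported as ``None`` (undefined), never
coerced to 0.  AUC is the rank statistic: the probability that a random
positive outscores a random negative, ties counting one half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "metrics", "auc",
           "head_sweep"]

DECISION_THRESHOLD = 0.5


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _check_binary(values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values)
    if not np.isin(values, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1")
    return values.astype(int)


def confusion(labels, predictions) -> ConfusionCounts:
    """Exact confusion counts; class 1 is the positive class."""
    y = _check_binary(labels, "labels")
    p = _check_binary(predictions, "predictions")
    if y.shape != p.shape:
        raise ValueError("labels and predictions differ in length")
    return ConfusionCounts(tp=int(((y == 1) & (p == 1)).sum()),
                           tn=int(((y == 0) & (p == 0)).sum()),
                           fp=int(((y == 0) & (p == 1)).sum()),
                           fn=int(((y == 1) & (p == 0)).sum()))


def metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """ACC/SEN/SPE/F1 from confusion counts; undefined ratios are None."""

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    acc = ratio(counts.tp + counts.tn, counts.n)
    sen = ratio(counts.tp, counts.tp + counts.fn)
    spe = ratio(counts.tn, counts.tn + counts.fp)
    precision = ratio(counts.tp, counts.tp + counts.fp)
    if precision is None or sen is None or precision + sen == 0:
        f1 = None
    else:
        f1 = 2 * precision * sen / (precision + sen)
    return {"ACC": acc, "SEN": sen, "SPE": spe, "F1": f1}


def auc(labels, scores) -> float:
    """Rank-based AUC of positive-class scores (Mann-Whitney statistic)."""
    y = _check_binary(labels, "labels")
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass(frozen=True)
class MetricReport:
    """ACC/SEN/SPE/AUC/F1 plus the underlying confusion counts."""

    acc: float | None
    sen: float | None
    spe: float | None
    auc: float | None
    f1: float | None
    confusion: ConfusionCounts
    n: int

    @classmethod
    def from_scores(cls, labels, scores,
                    threshold: float = DECISION_THRESHOLD) -> "MetricReport":
        """Build a report from positive-class probabilities."""
        y = _check_binary(labels, "labels")
        s = np.asarray(scores, dtype=float)
        preds = (s >= threshold).astype(int)
        counts = confusion(y, preds)
        m = metrics(counts)
        try:
            area = auc(y, s)
        except ValueError:
            area = None
        return cls(acc=m["ACC"], sen=m["SEN"], spe=m["SPE"], auc=area,
                   f1=m["F1"], confusion=counts, n=counts.n)

    def as_dict(self) -> dict:
        return {"ACC": self.acc, "SEN": self.sen, "SPE": self.spe,
                "AUC": self.auc, "F1": self.f1, "n": self.n,
                "TP": self.confusion.tp, "TN": self.confusion.tn,
                "FP": self.confusion.fp, "FN": self.confusion.fn}


def head_sweep(samples, head_counts, encoder_config=None, train_config=None,
               head_config=None):
    """Train and evaluate the full model once per attention head count.

    Returns a DataFrame with one row per head count (heads, ACC, AUC);
    deterministic for a fixed seed.  Raises if a count does not divide the
    fused feature dimension E = 2C.
    """
    import pandas as pd

    from . import trainer  # local import: trainer depends on this module

    rows = []
    for h in head_counts:
        report = trainer.run_variant("MMDDA", samples, heads=int(h),
                                     encoder_config=encoder_config,
                                     train_config=train_config,
                                     head_config=head_config)
        rows.append({"heads": int(h), "ACC": report.acc, "AUC": report.auc})
    return pd.DataFrame(rows)
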