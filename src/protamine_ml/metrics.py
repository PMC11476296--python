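"""Binary-classification metrics computed directly from confusion counts.

Implements accuracy, sensitivity (TPR/recall), precision (PPV), F1, false
positive rate, Cohen's kappa and the Matthews correlation coefficient from
their confusion-matrix definitions, plus ROC/AUC via the Mann-Whitney rank
statistic (exact under tied scores).  Ratios with a zero denominator are
reported as 0 and flagged rather than raising, so degenerate folds in a
cross-validation never abort a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts must describe at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricReport:
    """Metric bundle mirroring the evaluation tables' columns.

    ``auc`` is ``None`` when no scores were available.  ``flags`` names any
    metric whose denominator degenerated to zero (the metric is then 0 by
    convention).
    """

    acc: float
    recall: float
    precision: float
    f1: float
    fpr: float
    kappa: float
    mcc: float
    auc: float | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "acc": self.acc,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "kappa": self.kappa,
            "mcc": self.mcc,
            "auc": self.auc,
            "fpr": self.fpr,
        }
        if self.flags:
            out["flags"] = list(self.flags)
        return out


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Count TP/FP/FN/TN with class 1 as positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary (0/1)")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def _ratio(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """All seven scalar metrics from a confusion table.

    Kappa uses the marginal chance agreement
    ``Pe = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)] / N^2``; MCC is
    ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    n = counts.total
    flags: list[str] = []
    acc = (tp + tn) / n
    recall = _ratio(tp, tp + fn, "recall", flags)
    precision = _ratio(tp, tp + fp, "precision", flags)
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "f1", flags)
    fpr = _ratio(fp, fp + tn, "fpr", flags)

    po = acc
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    kappa = _ratio(po - pe, 1.0 - pe, "kappa", flags)

    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _ratio(float(tp) * tn - float(fp) * fn, mcc_den, "mcc", flags)
    return MetricReport(
        acc=acc, recall=recall, precision=precision, f1=f1,
        fpr=fpr, kappa=kappa, mcc=mcc, flags=flags,
    )


def roc_auc(scores, y_true) -> tuple[float, np.ndarray]:
    """AUC and ROC curve points from continuous scores.

    The AUC is the Mann-Whitney statistic — the probability that a random
    positive outscores a random negative, ties counting one half — computed
    via mid-ranks, which equals trapezoidal integration of the ROC curve
    over the full threshold sweep.  Curve points ``(fpr, tpr)`` are returned
    for plotting.  Raises on single-class truth.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    if scores.shape != y_true.shape:
        raise ValueError("scores and y_true lengths differ")
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes in y_true")
    ranks = rankdata(scores)  # mid-ranks under ties
    auc = (ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    # step-curve points over the descending unique-threshold sweep
    order = np.argsort(-scores, kind="stable")
    sorted_true = y_true[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_true == 1)
    fps = np.cumsum(sorted_true == 0)
    last_of_threshold = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tps[last_of_threshold] / n_pos]
    fpr = np.r_[0.0, fps[last_of_threshold] / n_neg]
    return float(auc), np.column_stack([fpr, tpr])
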