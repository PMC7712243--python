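"""Diagnostic performance metrics for the screening classifiers.

Positive = at-risk subject.  Rates are stored as fractions in [0, 1] and
formatted ×100 only at report time.  Undefined rates (zero denominator) are
reported as NaN with a flag rather than silently as 0, so that fold
averages are not distorted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .desat import AT_RISK, HEALTHY

__all__ = ["ConfusionCounts", "EvalReport", "rates", "roc_auc", "confusion_from_labels"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; positive class = at_risk."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts sum to zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalReport:
    """KPIs of one evaluation; rates as fractions, NaN where undefined."""

    sensitivity: float
    ppv: float
    specificity: float
    npv: float
    accuracy: float
    f1: float
    auc: float = math.nan
    roc_points: Optional[List[Tuple[float, float]]] = None
    counts: Optional[ConfusionCounts] = None
    undefined: Tuple[str, ...] = ()

    KPI_NAMES = ("auc", "accuracy", "sensitivity", "specificity", "ppv", "npv", "f1")

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.KPI_NAMES}
        if self.counts is not None:
            d["counts"] = {
                "tp": self.counts.tp,
                "fp": self.counts.fp,
                "tn": self.counts.tn,
                "fn": self.counts.fn,
            }
        if self.undefined:
            d["undefined"] = list(self.undefined)
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.as_dict(), **kw)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def rates(counts: ConfusionCounts) -> EvalReport:
    """KPIs from confusion counts.

    sensitivity = TP/(TP+FN); PPV = TP/(TP+FP); specificity = TN/(TN+FP);
    NPV = TN/(TN+FN); accuracy = (TP+TN)/N; F1 = 2TP/(2TP+FP+FN).
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    report = EvalReport(
        sensitivity=_ratio(tp, tp + fn),
        ppv=_ratio(tp, tp + fp),
        specificity=_ratio(tn, tn + fp),
        npv=_ratio(tn, tn + fn),
        accuracy=(tp + tn) / counts.total,
        f1=_ratio(2 * tp, 2 * tp + fp + fn),
        counts=counts,
    )
    undefined = tuple(
        k for k in ("sensitivity", "ppv", "specificity", "npv", "f1")
        if math.isnan(getattr(report, k))
    )
    report.undefined = undefined
    return report


def _binary_labels(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        return (arr == AT_RISK).astype(int)
    return arr.astype(int)


def confusion_from_labels(y_true: Sequence, y_pred: Sequence) -> ConfusionCounts:
    """Count TP/FP/TN/FN; accepts 0/1 or healthy/at_risk labels."""
    yt, yp = _binary_labels(y_true), _binary_labels(y_pred)
    return ConfusionCounts(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
    )


def roc_auc(scores: Sequence[float], labels: Sequence) -> Tuple[float, List[Tuple[float, float]]]:
    """Empirical ROC curve and trapezoidal AUC.

    Ties in the scores move along the curve in a single simultaneous step,
    which makes the trapezoidal area equal to the normalised Mann-Whitney
    U statistic.  Returns (auc, [(1-specificity, sensitivity), ...]).
    """
    y = _binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    if y.min() == y.max():
        raise ValueError("both classes must be present to compute ROC")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def summarize_folds(reports: Sequence[EvalReport]) -> pd.DataFrame:
    """Across-fold mean ± SD of each KPI, as a two-row table (fractions)."""
    data = {
        k: [getattr(r, k) for r in reports] for k in EvalReport.KPI_NAMES
    }
    df = pd.DataFrame(data)
    return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)}).T
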