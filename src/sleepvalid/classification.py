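"""Epoch-by-epoch sleep/wake classification agreement.

Sleep is the positive class everywhere.  Per-subject metrics follow the
standard 2×2 battery plus two less common ones:

* PABAK, the prevalence-and-bias-adjusted kappa, which for a 2×2 table
  reduces to 2·Po − 1 (observed agreement rescaled to [−1, 1]).  Kappa
  itself is badly depressed when one class dominates, as it does
  overnight where roughly three quarters of epochs are sleep.
* d′, the signal-detection separation Φ⁻¹(hit rate) − Φ⁻¹(false-alarm
  rate), with perfect rates clamped to 1/(2N) of the relevant class so
  the quantile stays finite.

The ROC/AUC is pooled over all subjects' epochs (one study-level curve),
computed by an explicit threshold sweep whose AUC equals the Mann–Whitney
pair-counting statistic with ties counted half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "ClassMetrics",
    "confusion_counts",
    "class_metrics",
    "pooled_roc",
    "cohort_class_summary",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2×2 tally with sleep as the positive class."""

    tp: int  # sleep predicted sleep
    fn: int  # sleep predicted wake
    fp: int  # wake predicted sleep
    tn: int  # wake predicted wake

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("negative confusion count")
        if self.total < 1:
            raise ValueError("empty confusion table")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class ClassMetrics:
    """Agreement metrics for one subject; NaN marks undefined rates."""

    sensitivity: float
    specificity: float
    accuracy: float
    balanced_accuracy: float
    precision: float
    kappa: float
    pabak: float
    dprime: float

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "precision": self.precision,
            "kappa": self.kappa,
            "pabak": self.pabak,
            "dprime": self.dprime,
        }


def confusion_counts(
    predicted: np.ndarray, truth: np.ndarray, mask: np.ndarray | None = None
) -> ConfusionCounts:
    """Tally predictions against truth (both boolean, True = sleep).

    ``mask`` selects the analyzable epochs; by default all epochs count.
    """
    pred = np.asarray(predicted, dtype=bool)
    tru = np.asarray(truth, dtype=bool)
    if pred.shape != tru.shape:
        raise ValueError("prediction/truth length mismatch")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        pred, tru = pred[mask], tru[mask]
    if pred.size == 0:
        raise ValueError("no analyzable epochs")
    tp = int(np.sum(pred & tru))
    fn = int(np.sum(~pred & tru))
    fp = int(np.sum(pred & ~tru))
    tn = int(np.sum(~pred & ~tru))
    return ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn)


def _clamped_quantile(rate: float, n_class: int) -> float:
    eps = 1.0 / (2.0 * n_class)
    return float(stats.norm.ppf(min(max(rate, eps), 1.0 - eps)))


def class_metrics(c: ConfusionCounts) -> ClassMetrics:
    """Derive the full metric battery from a confusion table.

    Rates whose marginal is empty (e.g. specificity on an all-sleep
    night) come out NaN, as does kappa when the truth has a single class.
    """
    n = c.total
    n_sleep = c.tp + c.fn
    n_wake = c.fp + c.tn
    n_pred_sleep = c.tp + c.fp

    sens = c.tp / n_sleep if n_sleep else math.nan
    spec = c.tn / n_wake if n_wake else math.nan
    acc = (c.tp + c.tn) / n
    bal = (sens + spec) / 2.0
    prec = c.tp / n_pred_sleep if n_pred_sleep else math.nan

    if n_sleep and n_wake:
        pe = (n_sleep * n_pred_sleep + n_wake * (n - n_pred_sleep)) / n**2
        kappa = (acc - pe) / (1.0 - pe) if pe < 1.0 else math.nan
        dprime = _clamped_quantile(sens, n_sleep) - _clamped_quantile(
            1.0 - spec, n_wake
        )
    else:
        kappa = math.nan
        dprime = math.nan
    pabak = 2.0 * acc - 1.0
    return ClassMetrics(
        sensitivity=sens, specificity=spec, accuracy=acc,
        balanced_accuracy=bal, precision=prec, kappa=kappa,
        pabak=pabak, dprime=dprime,
    )


def pooled_roc(
    scores: np.ndarray, truth: np.ndarray
) -> tuple[np.ndarray, float]:
    """ROC curve and trapezoidal AUC from pooled epoch scores.

    Sweeps the unique score values as thresholds (prediction =
    score ≥ threshold).  The trapezoidal area equals the Mann–Whitney
    statistic P(score_sleep > score_wake) + ½·P(tie).

    Returns ``(points, auc)`` where ``points`` is an (k, 2) array of
    (false positive rate, true positive rate) pairs from (0, 0) to
    (1, 1).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores/labels length mismatch")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one epoch of each class")

    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    # keep only the last point of each tied-score run
    last = np.r_[np.flatnonzero(np.diff(s_sorted)), s_sorted.size - 1]
    tpr = np.r_[0.0, tps[last] / n_pos]
    fpr = np.r_[0.0, fps[last] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def cohort_class_summary(
    subject_metrics: dict[str, ClassMetrics],
    pooled_scores: np.ndarray | None = None,
    pooled_truth: np.ndarray | None = None,
) -> pd.DataFrame:
    """Unweighted mean ± SD of each metric across subjects.

    Undefined (NaN) per-subject values are dropped from that metric's
    average, with the count of contributing subjects reported.  The AUC
    row, when score data are supplied, is pooled over all epochs rather
    than averaged across subjects.
    """
    if not subject_metrics:
        raise ValueError("no subjects")
    table = pd.DataFrame(
        {sid: m.as_dict() for sid, m in subject_metrics.items()}
    ).T
    rows = []
    if pooled_scores is not None and pooled_truth is not None:
        _, auc = pooled_roc(pooled_scores, pooled_truth)
        rows.append({"metric": "auc", "mean": auc, "sd": math.nan,
                     "n_subjects": len(table)})
    for col in table.columns:
        vals = table[col].dropna()
        rows.append({
            "metric": col,
            "mean": float(vals.mean()) if len(vals) else math.nan,
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "n_subjects": int(len(vals)),
        })
    return pd.DataFrame(rows, columns=["metric", "mean", "sd", "n_subjects"])
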