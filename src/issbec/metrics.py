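"""Confusion-matrix metrics and ROC analysis.

Nine standard binary metrics are computed directly from the confusion
counts: accuracy, sensitivity (recall), specificity, precision, F-measure,
Matthews correlation coefficient, negative predictive value, false-positive
rate and false-negative rate.  A ratio with zero denominator is reported as
0 and flagged rather than raised, since tiny test sets routinely produce
empty confusion cells.  Multiclass tasks are handled one-vs-rest per class
with macro-averaging (accuracy stays plain).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    positive_label: object = 1

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    counts: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_measure: float
    mcc: float
    npv: float
    fpr: float
    fnr: float
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "precision": self.precision,
            "f_measure": self.f_measure, "mcc": self.mcc, "npv": self.npv,
            "fpr": self.fpr, "fnr": self.fnr,
        }


def confusion(y_true, y_pred, positive_label) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if positive_label not in y_true:
        import warnings
        warnings.warn(f"positive label {positive_label!r} absent from y_true",
                      RuntimeWarning)
    tpos = y_true == positive_label
    ppos = y_pred == positive_label
    return ConfusionCounts(
        tp=int(np.sum(tpos & ppos)), fp=int(np.sum(~tpos & ppos)),
        tn=int(np.sum(~tpos & ~ppos)), fn=int(np.sum(tpos & ~ppos)),
        positive_label=positive_label,
    )


def _ratio(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    flags: list[str] = []
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    sens = _ratio(tp, tp + fn, "sensitivity", flags)
    spec = _ratio(tn, tn + fp, "specificity", flags)
    prec = _ratio(tp, tp + fp, "precision", flags)
    npv = _ratio(tn, tn + fn, "npv", flags)
    fnr = _ratio(fn, fn + tp, "fnr", flags)
    fpr = _ratio(fp, fp + tn, "fpr", flags)
    f_meas = _ratio(2 * prec * sens, prec + sens, "f_measure", flags)
    acc = _ratio(tp + tn, c.n, "accuracy", flags)
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _ratio(tn * tp - fn * fp, mcc_den, "mcc", flags)
    return MetricsReport(
        counts=c, accuracy=acc, sensitivity=sens, specificity=spec,
        precision=prec, f_measure=f_meas, mcc=mcc, npv=npv, fpr=fpr, fnr=fnr,
        undefined=flags,
    )


def evaluate(y_true, y_pred, positive_label) -> MetricsReport:
    return compute_metrics(confusion(y_true, y_pred, positive_label))


def macro_metrics(y_true, y_pred) -> dict[str, float]:
    """One-vs-rest macro average over classes; accuracy stays plain."""
    y_true = np.asarray(y_true)
    classes = np.unique(y_true)
    reports = [evaluate(y_true, y_pred, c) for c in classes]
    out = {
        k: float(np.mean([r.as_dict()[k] for r in reports]))
        for k in reports[0].as_dict()
    }
    out["accuracy"] = float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))
    return out


def roc_auc(y_true, positive_scores, positive_label):
    """ROC points by threshold sweep over the unique scores + trapezoid AUC.

    For the three-block ensemble the scores are vote fractions in
    {0, 1/3, 2/3, 1}, so the curve has at most five distinct points.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(positive_scores, float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    pos = y_true == positive_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    points = []
    for t in thresholds:
        pred = scores >= t
        tpr = np.sum(pred & pos) / n_pos
        fpr = np.sum(pred & ~pos) / n_neg
        points.append((float(fpr), float(tpr)))
    points = sorted(set(points))
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return points, auc
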