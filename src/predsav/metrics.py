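"""Binary-classification metrics and stratified cross-validation.

Labels are ±1 (+1 disease-associated, −1 neutral).  The metric suite is
sensitivity, specificity, precision, F1, accuracy, Matthews correlation
coefficient and ROC AUC; AUC is the Mann–Whitney pair statistic with the
midrank convention for ties, which makes it equal the trapezoidal area
under the ROC curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            TP=int(np.sum((y_true == 1) & (y_pred == 1))),
            TN=int(np.sum((y_true == -1) & (y_pred == -1))),
            FP=int(np.sum((y_true == -1) & (y_pred == 1))),
            FN=int(np.sum((y_true == 1) & (y_pred == -1))),
        )


@dataclass
class MetricReport:
    SEN: float
    SPE: float
    PRE: float
    F1: float
    ACC: float
    MCC: float
    AUC: float | None = None
    #: metrics whose denominator was zero and were set to 0 by convention
    zero_denominator: tuple = field(default_factory=tuple)

    def as_dict(self) -> dict:
        d = dict(SEN=self.SEN, SPE=self.SPE, PRE=self.PRE, F1=self.F1,
                 ACC=self.ACC, MCC=self.MCC)
        if self.AUC is not None:
            d["AUC"] = self.AUC
        return d


def _ratio(num, den, flags, name):
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def confusion_metrics(cc: ConfusionCounts) -> MetricReport:
    """Sensitivity, specificity, precision, F1, accuracy and MCC from counts.

    Zero denominators yield 0 by convention and are flagged in
    ``zero_denominator``.
    """
    tp, tn, fp, fn = cc.TP, cc.TN, cc.FP, cc.FN
    flags: list = []
    sen = _ratio(tp, tp + fn, flags, "SEN")
    spe = _ratio(tn, tn + fp, flags, "SPE")
    pre = _ratio(tp, tp + fp, flags, "PRE")
    f1 = _ratio(2 * sen * pre, sen + pre, flags, "F1")
    acc = _ratio(tp + tn, cc.total, flags, "ACC")
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den, flags, "MCC")
    return MetricReport(SEN=sen, SPE=spe, PRE=pre, F1=f1, ACC=acc, MCC=mcc,
                        zero_denominator=tuple(flags))


def roc_auc(y_true, scores) -> float:
    """Area under the ROC curve as the Mann–Whitney statistic:
    (concordant pairs + ½·tied pairs) / (n₊·n₋), via midranks."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must have the same length")
    pos = y_true == 1
    neg = y_true == -1
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # midranks
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def evaluate_predictions(y_true, scores, threshold: float = 0.0) -> MetricReport:
    """Full metric report from decision scores: labels at ``score ≥ threshold``
    (+1 on ties) plus the ranking AUC."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    y_pred = np.where(scores >= threshold, 1, -1)
    report = confusion_metrics(ConfusionCounts.from_predictions(y_true, y_pred))
    report.AUC = roc_auc(y_true, scores)
    return report


def roc_curve_points(y_true, scores):
    """ROC curve (FPR, TPR, threshold) as a DataFrame, e.g. for plotting or
    a TSV dump; trapezoidal area over these points equals :func:`roc_auc`."""
    import pandas as pd
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(np.asarray(y_true), np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def stratified_folds(y, folds: int = 5, seed: int = 0) -> list:
    """Seeded stratified partition; returns a list of (train_idx, test_idx)."""
    y = np.asarray(y)
    for cls in (-1, 1):
        if np.sum(y == cls) < folds:
            raise ValueError(f"class {cls:+d} has fewer than {folds} members")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def cross_validate(fm, learner_config: dict | None = None, folds: int = 5, seed: int = 0):
    """Stratified k-fold cross-validation of the gradient tree boosting
    learner on a feature matrix.

    Returns a dict with per-fold reports, their unweighted mean, the AUC of
    the pooled out-of-fold scores, and the pooled scores themselves.
    """
    from predsav.gtb import GradientTreeBoosting
    from predsav.selection import FeatureMatrix

    if not isinstance(fm, FeatureMatrix):
        raise TypeError("fm must be a FeatureMatrix")
    cfg = dict(n_trees=200, depth=3, learning_rate=0.1)
    cfg.update(learner_config or {})
    splits = stratified_folds(fm.y, folds=folds, seed=seed)
    pooled = np.zeros(len(fm.y))
    fold_reports = []
    for k, (tr, te) in enumerate(splits):
        model = GradientTreeBoosting(
            fm.X[tr], fm.y[tr], feature_names=fm.names, seed=seed + k, **cfg
        ).fit()
        scores = model.decision_function(fm.X[te])
        pooled[te] = scores
        fold_reports.append(evaluate_predictions(fm.y[te], scores))
    mean = MetricReport(
        **{
            m: float(np.mean([getattr(r, m) for r in fold_reports]))
            for m in ("SEN", "SPE", "PRE", "F1", "ACC", "MCC", "AUC")
        }
    )
    return dict(
        folds=fold_reports,
        mean=mean,
        pooled_auc=roc_auc(fm.y, pooled),
        pooled_scores=pooled,
    )
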