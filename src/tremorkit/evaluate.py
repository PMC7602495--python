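"""Clinically oriented evaluation: LOSO folds, ROC metrics, weak-label
agreement and percentage-of-tremor-time.

Aggregate performance is the mean of per-subject AUCs under
leave-one-subject-out cross-validation (each subject is scored by a model
that never saw their data).  ``FPR@0.9TPR`` reports the false-positive
rate at 90 % sensitivity, interpolated linearly between ROC points.
Differences between AUCs can be tested with the Hanley-McNeil standard
error.  Window predictions aggregate into the percentage-of-tremor-time
biomarker over fixed periods, which maps onto the three diary levels
(<33 % -> almost none, 33-66 % -> half the time, >66 % -> almost always;
midpoints 16.6 / 50 / 83.3 % for the inverse map); agreement with reported
diary labels is measured by Spearman's rank correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "LABEL_ORDER",
    "EvalReport",
    "loso_folds",
    "roc_metrics",
    "hanley_se",
    "hanley_auc_significance",
    "percent_tremor",
    "percent_to_weak_label",
    "weak_label_to_percent",
    "weak_agreement",
    "loso_evaluate",
]

#: ordinal encoding of the three diary levels
LABEL_ORDER = ("almost_none", "half_the_time", "almost_always")
_LABEL_MIDPOINTS = {"almost_none": 16.6, "half_the_time": 50.0, "almost_always": 83.3}


@dataclass
class EvalReport:
    """Per-subject and aggregate LOSO results."""

    per_subject_auc: dict
    per_subject_fpr_at_09: dict
    mean_auc: float
    mean_fpr_at_09: float
    config: dict = field(default_factory=dict)


def loso_folds(subjects) -> list:
    """Leave-one-subject-out folds: (train_subjects, test_subject) pairs.

    Subjects are sorted, so the fold layout does not depend on input order.
    """
    uniq = sorted(set(subjects))
    if len(uniq) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    return [([s for s in uniq if s != test], test) for test in uniq]


def roc_metrics(scores, labels) -> tuple:
    """(AUC, FPR at 0.90 TPR) from window scores and binary labels.

    AUC is the trapezoidal area under the empirical ROC; the FPR at 90 %
    sensitivity is linearly interpolated between adjacent ROC points.
    """
    labels = np.asarray(labels).astype(int).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC metrics undefined: labels contain a single class")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    fpr_at = float(np.interp(0.90, tpr, fpr))
    return auc, fpr_at


def hanley_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of an empirical AUC."""
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least 2 samples of each class")
    if not 0 < auc < 1:
        raise ValueError("AUC must lie in (0, 1)")
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(var))


def hanley_auc_significance(
    auc_a: float, auc_b: float, n_pos: int, n_neg: int
) -> float:
    """Two-sided p-value for a difference of two independent AUCs.

    Both AUCs are assumed measured on samples of the given class sizes;
    the z statistic uses the Hanley-McNeil standard error of each.
    """
    se = np.sqrt(hanley_se(auc_a, n_pos, n_neg) ** 2 + hanley_se(auc_b, n_pos, n_neg) ** 2)
    if se == 0:
        return 1.0 if auc_a == auc_b else 0.0
    z = (auc_a - auc_b) / se
    return float(2 * stats.norm.sf(abs(z)))


def percent_tremor(window_preds, period_s: float, hop_s: float = 1.0) -> np.ndarray:
    """Percentage of tremor-classified windows per consecutive period.

    ``window_preds`` are time-ordered binary window predictions at a fixed
    hop (1 s by default).  The predictions are chunked into consecutive
    periods of ``period_s`` seconds; each period reports
    100 * tremor windows / windows in period.  A trailing partial period is
    included if non-empty; use ``period_s`` >= session length for a single
    whole-session percentage.
    """
    preds = np.asarray(window_preds).astype(float).ravel()
    per = max(1, int(round(period_s / hop_s)))
    out = []
    for start in range(0, len(preds), per):
        chunk = preds[start : start + per]
        if len(chunk):
            out.append(100.0 * float(np.mean(chunk)))
    return np.asarray(out)


def percent_to_weak_label(pct: float) -> str:
    """Map a tremor percentage onto the 3-level diary label.

    Boundaries: below 33 % -> almost none, 33-66 % inclusive -> half the
    time, above 66 % -> almost always.
    """
    if not 0 <= pct <= 100:
        raise ValueError("percentage must lie in [0, 100]")
    if pct < 33.0:
        return "almost_none"
    if pct <= 66.0:
        return "half_the_time"
    return "almost_always"


def weak_label_to_percent(label: str) -> float:
    """Inverse map: the midpoint percentage of each diary level."""
    try:
        return _LABEL_MIDPOINTS[label]
    except KeyError:
        raise ValueError(f"unknown weak label {label!r}") from None


def _ordinal(seq) -> np.ndarray:
    arr = []
    for v in seq:
        arr.append(LABEL_ORDER.index(v) if isinstance(v, str) else int(v))
    return np.asarray(arr)


def weak_agreement(predicted_labels, reported_labels) -> tuple:
    """Spearman rank correlation between predicted and reported diary labels.

    Labels may be strings or ordinals 0/1/2.  Ties receive average ranks;
    the p-value uses the t approximation.  A constant sequence leaves the
    correlation undefined: (nan, nan) is returned with a warning.
    """
    a = _ordinal(predicted_labels)
    b = _ordinal(reported_labels)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need >= 3 paired intervals")
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        warnings.warn("constant label sequence: Spearman correlation undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def loso_evaluate(
    subject_ids, X, y, train_fn, predict_fn
) -> EvalReport:
    """Run LOSO cross-validation with caller-supplied train/predict hooks.

    ``train_fn(X_train, y_train, test_subject)`` returns a fitted model;
    ``predict_fn(model, X_test)`` returns window scores.  Folds whose test
    labels are single-class (AUC undefined) or whose training labels are
    single-class (no classifier can be fitted) are skipped.
    """
    subject_ids = np.asarray(subject_ids)
    X = np.asarray(X)
    y = np.asarray(y).astype(int).ravel()
    aucs, fprs = {}, {}
    for train_subjects, test_subject in loso_folds(subject_ids):
        te = subject_ids == test_subject
        tr = ~te
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            continue
        model = train_fn(X[tr], y[tr], test_subject)
        scores = predict_fn(model, X[te])
        auc, fpr = roc_metrics(scores, y[te])
        aucs[str(test_subject)] = auc
        fprs[str(test_subject)] = fpr
    if not aucs:
        raise ValueError("no subject had both classes in its test data")
    return EvalReport(
        per_subject_auc=aucs,
        per_subject_fpr_at_09=fprs,
        mean_auc=float(np.mean(list(aucs.values()))),
        mean_fpr_at_09=float(np.mean(list(fprs.values()))),
    )
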