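"""Weakly supervised training via stratified multiple-instance learning.

Self-reported diary entries rate the amount of tremor in 5-minute
intervals on three levels (*almost none*, *half the time*, *almost
always*).  The MIL loop turns these interval-level (bag) labels into
window-level training sets by iterating three steps:

1. score every 3-s window in each interval with the current classifier
   (sigmoid pseudo-probabilities),
2. sort the windows of each interval by score,
3. select windows for retraining: the bottom 50 % (labeled 0) for *almost
   none*, the top 50 % (labeled 1) for *almost always*, and the bottom
   25 % plus top 25 % for *half the time*.

Because no classifier exists at the first iteration, the initial ranking
uses the unsupervised tremor-energy score from the non-negative tremor
factorization.  The iteration at which to stop is chosen on a validation
subset of training entries (20 % of subjects), scored by the Spearman
correlation between predicted and reported weak labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .evaluate import percent_to_weak_label, weak_agreement, LABEL_ORDER
from .models import ClassifierModel, predict_scores, train_classifier

__all__ = ["WeakLabelEntry", "select_instances", "mil_train", "MilResult"]

_MIN_WINDOWS = 4


@dataclass
class WeakLabelEntry:
    """One 5-minute self-report interval with a 3-level tremor label."""

    subject_id: str
    interval: tuple  # (start_s, end_s), 300 s long
    label: str  # almost_none | half_the_time | almost_always
    window_indices: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __post_init__(self) -> None:
        if self.label not in LABEL_ORDER:
            raise ValueError(f"unknown weak label {self.label!r}")
        s, e = self.interval
        if not np.isclose(e - s, 300.0):
            raise ValueError("weak-label interval must be 300 s long")
        self.window_indices = np.asarray(self.window_indices, dtype=int)


def assign_windows(
    entries: list, window_start_s: np.ndarray, subject_ids: np.ndarray
) -> list:
    """Attach to each entry the windows whose start lies in its interval."""
    out = []
    for e in entries:
        mask = (
            (subject_ids == e.subject_id)
            & (window_start_s >= e.interval[0])
            & (window_start_s < e.interval[1])
        )
        out.append(
            WeakLabelEntry(e.subject_id, e.interval, e.label, np.flatnonzero(mask))
        )
    return out


def select_instances(scores: np.ndarray, label: str) -> tuple:
    """Select windows of one interval for retraining, per its weak label.

    Returns (indices into ``scores``, assigned binary labels).  Counts use
    floor with a minimum of 1; sorting is stable so ties fall back to
    window order.  Requires at least 4 windows.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n < _MIN_WINDOWS:
        raise ValueError(f"interval has {n} windows; need >= {_MIN_WINDOWS}")
    order = np.argsort(scores, kind="stable")  # ascending; ties by index
    if label == "almost_none":
        k = max(1, n // 2)
        idx = order[:k]
        lab = np.zeros(k, dtype=int)
    elif label == "almost_always":
        k = max(1, n // 2)
        idx = order[-k:]
        lab = np.ones(k, dtype=int)
    elif label == "half_the_time":
        k = max(1, n // 4)
        idx = np.concatenate([order[:k], order[-k:]])
        lab = np.concatenate([np.zeros(k, dtype=int), np.ones(k, dtype=int)])
    else:
        raise ValueError(f"unknown weak label {label!r}")
    return idx, lab


@dataclass
class MilResult:
    """Final MIL model plus the per-iteration validation trace."""

    model: ClassifierModel
    selected_iteration: int  # 0 = model trained on the energy-ranked selection
    val_trace: list  # validation Spearman rho per iteration
    n_iterations_run: int


def _predict_entry_labels(
    entries: list, scores: np.ndarray, threshold: float = 0.5
) -> list:
    labels = []
    for e in entries:
        s = scores[e.window_indices]
        pct = 100.0 * float(np.mean(s > threshold)) if len(s) else 0.0
        labels.append(percent_to_weak_label(pct))
    return labels


def _val_metric(entries: list, scores: np.ndarray) -> float:
    pred = _predict_entry_labels(entries, scores)
    given = [e.label for e in entries]
    if len(set(given)) < 2:
        return -1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, _ = weak_agreement(pred, given)
    return -1.0 if np.isnan(rho) else float(rho)


def mil_train(
    entries: list,
    features: np.ndarray,
    energies: np.ndarray,
    base: str = "mlp",
    max_iters: int = 10,
    seed: int = 0,
    patience: int = 3,
    epochs: int = 30,
) -> MilResult:
    """Run the stratified MIL loop over weakly labeled intervals.

    ``entries`` must carry window indices into ``features`` (per-window
    feature matrix) and ``energies`` (per-window NTF tremor-energy scores
    used for the iteration-0 ranking).  Each iteration selects instances
    from every usable training entry, retrains the base classifier on the
    union of selections, and rescores all windows.  Training stops when the
    validation Spearman correlation has not improved for ``patience``
    iterations or at ``max_iters``; the model from the best validation
    iteration is returned.
    """
    features = np.asarray(features, dtype=float)
    energies = np.asarray(energies, dtype=float)
    entries = [e for e in entries if len(e.window_indices) >= _MIN_WINDOWS]
    if not entries:
        raise ValueError("no usable weak-label entries (>= 4 windows each)")
    for e in entries:
        if len(e.window_indices) < _MIN_WINDOWS:
            warnings.warn(f"skipping interval {e.interval} with too few windows")

    rng = np.random.default_rng(seed)
    subjects = sorted({e.subject_id for e in entries})
    if len(subjects) >= 2:
        shuffled = list(subjects)
        rng.shuffle(shuffled)
        n_val = max(1, int(round(0.2 * len(subjects))))
        val_subjects = set(shuffled[:n_val])
    else:
        val_subjects = set()
    train_entries = [e for e in entries if e.subject_id not in val_subjects]
    val_entries = [e for e in entries if e.subject_id in val_subjects]
    if not train_entries:
        train_entries, val_entries = entries, []
    if len({e.label for e in train_entries}) < 2:
        warnings.warn("all training entries share one weak label")

    scores = energies.copy()  # iteration-0 ranking: unsupervised tremor energy
    best_model, best_metric, best_iter, bad = None, -np.inf, 0, 0
    trace: list = []
    iterations_run = 0
    for it in range(max_iters + 1):
        sel_idx, sel_lab = [], []
        for e in train_entries:
            idx, lab = select_instances(scores[e.window_indices], e.label)
            sel_idx.append(e.window_indices[idx])
            sel_lab.append(lab)
        X = features[np.concatenate(sel_idx)]
        y = np.concatenate(sel_lab)
        if len(np.unique(y)) < 2:
            warnings.warn("degenerate selection: one class only; stopping MIL")
            break
        model = train_classifier(X, y, kind=base, seed=seed, epochs=epochs)
        scores = predict_scores(model, features)
        metric = _val_metric(val_entries, scores) if val_entries else _val_metric(
            train_entries, scores
        )
        trace.append(metric)
        iterations_run = it + 1
        if metric > best_metric + 1e-12:
            best_model, best_metric, best_iter, bad = model, metric, it, 0
        else:
            bad += 1
            if bad >= patience:
                break
    if best_model is None:
        raise ValueError("MIL training failed: no model could be fitted")
    return MilResult(
        model=best_model,
        selected_iteration=best_iter,
        val_trace=trace,
        n_iterations_run=iterations_run,
    )
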