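"""End-to-end glue: cohort/recordings -> windows -> spectra -> features.

These helpers wire the stage modules together for the common experiment
layouts (LOSO evaluation of a feature set + classifier, weakly supervised
MIL training) without adding any behavior of their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import features as feats
from . import ntf
from .evaluate import EvalReport, loso_evaluate
from .mil import WeakLabelEntry
from .models import predict_scores, train_classifier
from .preprocess import (
    AccelRecording,
    TremorIntervalSet,
    WindowSet,
    highpass_gravity,
    label_windows,
    make_windows,
    resample_to_50hz,
)

__all__ = ["Dataset", "process_recording", "build_dataset", "loso_feature_auc"]


def process_recording(
    rec: AccelRecording, intervals: TremorIntervalSet | None = None
) -> WindowSet:
    """Standard preprocessing chain: 50 Hz, gravity removed, windowed, labeled."""
    rec = resample_to_50hz(rec)
    rec = highpass_gravity(rec)
    ws = make_windows(rec)
    if intervals is not None and len(ws):
        ws = label_windows(ws, intervals)
    return ws


@dataclass
class Dataset:
    """Window-level arrays pooled over all subject-hand recordings."""

    X: np.ndarray  # (n, d) feature matrix of the primary feature set
    y: np.ndarray  # (n,) binary window labels
    subject_ids: np.ndarray  # (n,) subject of each window
    group_ids: np.ndarray  # (n,) "subject/hand" of each window
    window_start_s: np.ndarray  # (n,)
    energies: np.ndarray  # (n,) NTF tremor-energy score
    entries: list = field(default_factory=list)  # WeakLabelEntry with global indices
    features: dict = field(default_factory=dict)  # set_id -> (n, d) matrix
    tnt_stack: np.ndarray | None = None  # (n, 9, 128) for the spectral CNN
    windows: np.ndarray | None = None  # (n, 150, 3) raw filtered windows

    def with_features(self, set_id: str) -> "Dataset":
        """A shallow copy whose primary matrix ``X`` is another extracted set."""
        from dataclasses import replace

        return replace(self, X=self.features[set_id])


def build_dataset(
    cohort,
    feature_set="mfcc_tnt",
    personalize: bool = True,
    n_iter: int = 100,
    keep_windows: bool = False,
    keep_tnt_stack: bool = False,
) -> Dataset:
    """Preprocess and featurize every recording of a synthetic cohort.

    Runs the NTF stage per subject-hand (personalized on that recording's
    windows), extracts the requested feature set (or several sets in one
    pass: pass a list; the first one becomes ``Dataset.X``), pools windows
    across recordings and resolves each diary entry's windows to global
    indices.
    """
    sets = [feature_set] if isinstance(feature_set, str) else list(feature_set)
    X_parts = {s: [] for s in sets}
    y_parts, subj, group, starts, energy = [], [], [], [], []
    entries_out: list = []
    tnt_parts, win_parts = [], []
    offset = 0
    for rec in cohort.recordings:
        key = (rec.subject_id, rec.hand)
        ws = process_recording(rec, cohort.intervals[key])
        if len(ws) == 0:
            continue
        tnt = ntf.analyze_windows(ws, personalize_dict=personalize, n_iter=n_iter)
        energy.append(tnt.energy)
        for s in sets:
            X_parts[s].append(feats.feature_matrix(ws, s, tnt=tnt).values)
        y_parts.append(ws.label)
        subj.append(np.full(len(ws), rec.subject_id, dtype=object))
        group.append(np.full(len(ws), f"{rec.subject_id}/{rec.hand}", dtype=object))
        starts.append(ws.window_start_s)
        if keep_tnt_stack:
            tnt_parts.append(tnt.stacked())
        if keep_windows:
            win_parts.append(ws.windows)
        for e in cohort.weak_labels.get(key, []):
            mask = (ws.window_start_s >= e.interval[0]) & (
                ws.window_start_s < e.interval[1]
            )
            entries_out.append(
                WeakLabelEntry(
                    subject_id=e.subject_id,
                    interval=e.interval,
                    label=e.label,
                    window_indices=np.flatnonzero(mask) + offset,
                )
            )
        offset += len(ws)
    feature_mats = {s: np.concatenate(X_parts[s]) for s in sets}
    return Dataset(
        X=feature_mats[sets[0]],
        y=np.concatenate(y_parts),
        subject_ids=np.concatenate(subj),
        group_ids=np.concatenate(group),
        window_start_s=np.concatenate(starts),
        energies=np.concatenate(energy),
        entries=entries_out,
        features=feature_mats,
        tnt_stack=np.concatenate(tnt_parts) if tnt_parts else None,
        windows=np.concatenate(win_parts) if win_parts else None,
    )


def loso_feature_auc(
    ds: Dataset, classifier: str = "mlp", seed: int = 0, epochs: int = 40
) -> EvalReport:
    """LOSO evaluation of a classifier on a built dataset.

    The 1-d band-energy feature is scored directly (thresholdless AUC over
    the score range); other feature sets train the requested classifier
    per fold.
    """
    if ds.X.shape[1] == 1:
        return loso_evaluate(
            ds.subject_ids,
            ds.X,
            ds.y,
            train_fn=lambda X, y, s: None,
            predict_fn=lambda m, X: X[:, 0],
        )
    return loso_evaluate(
        ds.subject_ids,
        ds.X,
        ds.y,
        train_fn=lambda X, y, s: train_classifier(X, y, classifier, seed=seed, epochs=epochs),
        predict_fn=predict_scores,
    )
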