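"""Accelerometer ingest, resampling, gravity removal and windowing.

The detection pipeline operates on triaxial wrist accelerometer recordings.
All downstream stages (spectral factorization, feature sets, classifiers)
share the conventions fixed here:

* working sample rate 50 Hz (raw device recordings, typically 100 Hz, are
  downsampled with anti-alias filtering),
* gravity removed with a zero-phase third-order Butterworth high-pass at
  0.3 Hz,
* 3-second analysis windows (150 samples) with a 1-second hop (2 s overlap),
* a single 128-point amplitude-spectrum grid covering 0-25 Hz, obtained by
  zero-padding the Hamming-tapered window to 256 points and keeping the
  first 128 one-sided bins.

A window is labeled tremor when more than 50 % of it (strictly more than
1.5 s) overlaps annotated tremor intervals; exactly 50 % counts as
non-tremor.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "FS",
    "WINDOW_SAMPLES",
    "HOP_SAMPLES",
    "N_FFT",
    "N_GRID",
    "FREQ_GRID",
    "AccelRecording",
    "TremorIntervalSet",
    "WindowSet",
    "load_recording",
    "save_recording",
    "load_intervals",
    "save_intervals",
    "resample_to_50hz",
    "highpass_gravity",
    "make_windows",
    "label_windows",
    "amplitude_spectrum",
]

#: working sample rate after downsampling, Hz
FS = 50.0
#: samples per 3-s analysis window at 50 Hz
WINDOW_SAMPLES = 150
#: hop between consecutive windows (1 s)
HOP_SAMPLES = 50
#: FFT length used for the shared spectral grid (150-sample window, zero-padded)
N_FFT = 256
#: number of one-sided spectral points kept (0 to 24.8 Hz)
N_GRID = 128
#: the shared frequency grid, Hz
FREQ_GRID = np.arange(N_GRID) * FS / N_FFT

_HANDS = ("left", "right")


@dataclass
class AccelRecording:
    """Timestamped triaxial acceleration for one wrist of one subject."""

    subject_id: str
    hand: str
    sample_rate: float
    samples: np.ndarray  # (n, 3) float
    start_time: float = 0.0
    units: str = "g"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if self.hand not in _HANDS:
            raise ValueError(f"hand must be one of {_HANDS}, got {self.hand!r}")
        if np.isnan(self.samples).any():
            raise ValueError("recording contains NaN samples; split gaps first")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate


@dataclass
class TremorIntervalSet:
    """Half-open [start, end) tremor-event intervals for one hand.

    Overlapping or touching intervals are merged on construction so the set
    is always sorted and disjoint.
    """

    intervals: list
    hand: str = "left"

    def __post_init__(self) -> None:
        if self.hand not in _HANDS:
            raise ValueError(f"hand must be one of {_HANDS}")
        ivs = []
        for s, e in self.intervals:
            if not e > s:
                raise ValueError(f"interval end must exceed start: ({s}, {e})")
            ivs.append((float(s), float(e)))
        ivs.sort()
        merged: list = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        self.intervals = merged

    def overlap(self, start: float, end: float) -> float:
        """Total overlap (seconds) of [start, end) with the interval set."""
        total = 0.0
        for s, e in self.intervals:
            total += max(0.0, min(e, end) - max(s, start))
        return total

    def total_duration(self) -> float:
        return sum(e - s for s, e in self.intervals)


@dataclass
class WindowSet:
    """3-s / 1-s-hop windows cut from one filtered 50 Hz recording."""

    windows: np.ndarray  # (n_windows, 150, 3)
    window_start_s: np.ndarray  # (n_windows,)
    subject_id: str
    hand: str
    label: np.ndarray | None = None  # optional (n_windows,) binary

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.ndim != 3 or self.windows.shape[1:] != (WINDOW_SAMPLES, 3):
            raise ValueError(f"windows must be (n, {WINDOW_SAMPLES}, 3)")
        self.window_start_s = np.asarray(self.window_start_s, dtype=float)
        if self.label is not None:
            self.label = np.asarray(self.label, dtype=int)

    def __len__(self) -> int:
        return self.windows.shape[0]

    def spectra(self, taper: str = "hamming") -> np.ndarray:
        """Amplitude spectra of all windows, shape (n, 3, 128)."""
        if len(self) == 0:
            return np.zeros((0, 3, N_GRID))
        return np.stack([amplitude_spectrum(w, taper) for w in self.windows])


def load_recording(path, fmt: str = "csv") -> AccelRecording:
    """Read a recording CSV (columns ``t,x,y,z``; t in seconds).

    The sample rate is inferred as the median of 1/dt; timestamp drift above
    1 % of the median step is rejected.  An optional JSON sidecar
    (``<stem>.json``) provides subject_id, hand and units.
    """
    if fmt != "csv":
        raise ValueError(f"unsupported format {fmt!r}")
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"t", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df[["t", "x", "y", "z"]].isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{path}: NaN/malformed values at data row {row}")
    t = df["t"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if (dt <= 0).any():
        row = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise ValueError(f"{path}: non-monotonic time at data row {row}")
    med = float(np.median(dt))
    if np.abs(dt - med).max() > 0.01 * med:
        raise ValueError(f"{path}: sample-interval drift exceeds 1%")
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return AccelRecording(
        subject_id=str(meta.get("subject_id", path.stem)),
        hand=meta.get("hand", "left"),
        sample_rate=1.0 / med,
        samples=df[["x", "y", "z"]].to_numpy(dtype=float),
        start_time=float(t[0]),
        units=meta.get("units", "g"),
    )


def save_recording(rec: AccelRecording, path) -> None:
    """Write a recording as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "t": rec.times,
            "x": rec.samples[:, 0],
            "y": rec.samples[:, 1],
            "z": rec.samples[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    path.with_suffix(".json").write_text(
        json.dumps(
            {
                "subject_id": rec.subject_id,
                "hand": rec.hand,
                "units": rec.units,
                "sample_rate": rec.sample_rate,
            },
            indent=1,
        )
    )


def load_intervals(path, hand: str | None = None) -> TremorIntervalSet:
    """Read tremor-event intervals from JSON: ``[{"start","end","hand"}]``."""
    entries = json.loads(Path(path).read_text())
    if hand is None:
        hands = {e.get("hand", "left") for e in entries}
        hand = sorted(hands)[0] if hands else "left"
    ivs = [(e["start"], e["end"]) for e in entries if e.get("hand", hand) == hand]
    return TremorIntervalSet(intervals=ivs, hand=hand)


def save_intervals(tiv: TremorIntervalSet, path) -> None:
    Path(path).write_text(
        json.dumps(
            [{"start": s, "end": e, "hand": tiv.hand} for s, e in tiv.intervals],
            indent=1,
        )
    )


def resample_to_50hz(rec: AccelRecording) -> AccelRecording:
    """Downsample a recording to the 50 Hz working rate.

    Exact 2:1 inputs (100 Hz) are decimated by 2 with a zero-phase
    anti-alias filter; other rates use polyphase rational resampling.
    Rates below 50 Hz are rejected.
    """
    if rec.sample_rate < FS - 1e-9:
        raise ValueError(
            f"sample rate {rec.sample_rate:g} Hz is below the 50 Hz working rate"
        )
    if math.isclose(rec.sample_rate, FS, rel_tol=1e-9):
        return rec
    if math.isclose(rec.sample_rate, 2 * FS, rel_tol=1e-9):
        out = signal.decimate(rec.samples, 2, axis=0, zero_phase=True)
    else:
        frac = Fraction(FS / rec.sample_rate).limit_denominator(1000)
        out = signal.resample_poly(rec.samples, frac.numerator, frac.denominator, axis=0)
    return replace(rec, sample_rate=FS, samples=out)


def highpass_gravity(rec: AccelRecording) -> AccelRecording:
    """Remove gravity with a zero-phase 3rd-order Butterworth high-pass, 0.3 Hz.

    Filtering is forward-backward (zero phase) because the analysis is
    offline; a causal filter would shift events against their labels by the
    group delay.
    """
    if not math.isclose(rec.sample_rate, FS, rel_tol=1e-9):
        raise ValueError("highpass_gravity expects a 50 Hz recording")
    if rec.n_samples < WINDOW_SAMPLES:
        raise ValueError("recording shorter than 3 s; too short to filter")
    sos = signal.butter(3, 0.3, btype="highpass", fs=FS, output="sos")
    out = signal.sosfiltfilt(sos, rec.samples, axis=0)
    return replace(rec, samples=out)


def make_windows(rec: AccelRecording) -> WindowSet:
    """Cut a filtered 50 Hz recording into 150-sample windows, 50-sample hop.

    The trailing partial window is discarded; recordings under 3 s yield an
    empty set.
    """
    if not math.isclose(rec.sample_rate, FS, rel_tol=1e-9):
        raise ValueError("make_windows expects a 50 Hz recording")
    n = rec.n_samples
    n_win = max(0, (n - WINDOW_SAMPLES) // HOP_SAMPLES + 1)
    if n_win == 0:
        return WindowSet(
            windows=np.zeros((0, WINDOW_SAMPLES, 3)),
            window_start_s=np.zeros(0),
            subject_id=rec.subject_id,
            hand=rec.hand,
        )
    idx = np.arange(n_win)[:, None] * HOP_SAMPLES + np.arange(WINDOW_SAMPLES)[None, :]
    return WindowSet(
        windows=rec.samples[idx],
        window_start_s=rec.start_time + np.arange(n_win) * (HOP_SAMPLES / FS),
        subject_id=rec.subject_id,
        hand=rec.hand,
    )


def label_windows(ws: WindowSet, tiv: TremorIntervalSet) -> WindowSet:
    """Attach binary tremor labels: 1 iff overlap with events exceeds 1.5 s.

    Strictly-more-than-50 % overlap is required; a window overlapping exactly
    half is labeled non-tremor.
    """
    if ws.hand != tiv.hand:
        raise ValueError(f"hand mismatch: windows={ws.hand!r} intervals={tiv.hand!r}")
    win_len = WINDOW_SAMPLES / FS
    labels = np.zeros(len(ws), dtype=int)
    for i, s in enumerate(ws.window_start_s):
        labels[i] = 1 if tiv.overlap(s, s + win_len) > win_len / 2 else 0
    return WindowSet(
        windows=ws.windows,
        window_start_s=ws.window_start_s,
        subject_id=ws.subject_id,
        hand=ws.hand,
        label=labels,
    )


def amplitude_spectrum(window: np.ndarray, taper: str = "hamming") -> np.ndarray:
    """Per-axis one-sided amplitude spectrum on the shared 128-point grid.

    The 150-sample window is tapered (Hamming by default), zero-padded to 256
    points and the magnitudes of the first 128 one-sided FFT bins (0 to
    24.8 Hz) are returned, shape (3, 128).  The identical grid is used by the
    PSD features, the tremor factorization and the spectral CNN inputs.
    """
    window = np.asarray(window, dtype=float)
    if window.shape != (WINDOW_SAMPLES, 3):
        raise ValueError(f"window must be ({WINDOW_SAMPLES}, 3)")
    if taper == "hamming":
        w = np.hamming(WINDOW_SAMPLES)
    elif taper == "none":
        w = np.ones(WINDOW_SAMPLES)
    else:
        raise ValueError(f"unknown taper {taper!r}")
    spec = np.abs(np.fft.rfft(window * w[:, None], n=N_FFT, axis=0))
    return spec[:N_GRID].T
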