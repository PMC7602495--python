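"""Synthetic wrist-accelerometer cohorts for exercising the pipeline.

No public dataset pairs continuous wrist acceleration with tremor-event
annotations and 3-level diary labels, so the generator emulates the
statistical structure the pipeline assumes:

* recordings at 100 Hz (so the 2:1 downsampling path is exercised), in g;
* a gravity component with slow orientation drift (below 0.3 Hz);
* background activities of daily living (ADL): Gaussian noise low-passed
  at 3 Hz, where the energy of normal movement concentrates;
* optional broadband 3-9 Hz "confounder" bursts -- vigorous rhythmic-ish
  activity without harmonic structure -- that overlap the tremor band and
  make the plain band-energy feature imperfect;
* tremor bursts: a sinusoid at the subject's base frequency f0 with
  harmonics at 2*f0 and 3*f0 (amplitudes 1 : 0.5 : 0.25), Hann-shaped
  on/off envelopes, random phase per axis, alternating with exponential
  off periods so the expected coverage matches the subject's prevalence.
  The instantaneous frequency wanders slowly around f0 (about +-0.3 Hz)
  and each harmonic's amplitude fluctuates, as physiological tremor does,
  which broadens the spectral lines beyond pure sinusoid bins;
* white sensor noise;
* diary entries: one 5-minute interval per entry period whose true tremor
  fraction maps to the 3 levels (<33 / 33-66 / >66 %), optionally
  perturbed one level with probability ``label_noise``.

Returned interval annotations are the exact burst extents, so
window-level ground truth and percentage-of-tremor bookkeeping are exact.
All randomness flows from one seed; identical seeds give bit-identical
cohorts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .evaluate import percent_to_weak_label, LABEL_ORDER
from .mil import WeakLabelEntry
from .preprocess import AccelRecording, TremorIntervalSet, save_intervals, save_recording

__all__ = ["SubjectProfile", "Cohort", "gen_recording", "gen_weak_labels", "gen_cohort", "save_cohort"]

_RAW_FS = 100.0


@dataclass
class SubjectProfile:
    """Ground-truth tremor characteristics of one simulated subject-hand."""

    subject_id: str
    f0: float = 5.0  # tremor base frequency, Hz
    harmonic_amps: tuple = (0.15, 0.075, 0.0375)  # g, at f0 / 2f0 / 3f0
    tremor_prevalence: float = 0.3  # fraction of time in tremor
    tremor_burst_duration: float = 20.0  # mean burst length, s
    adl_level: float = 0.05  # RMS of sub-3 Hz background motion, g
    confounder_coverage: float = 0.05  # fraction of time in 3-9 Hz broadband bursts
    label_noise: float = 0.0  # probability a diary label is off by one level

    def __post_init__(self) -> None:
        if not 3.0 <= self.f0 <= 9.0:
            raise ValueError("f0 must lie in [3, 9] Hz")
        if not 0.0 <= self.tremor_prevalence <= 1.0:
            raise ValueError("tremor_prevalence must lie in [0, 1]")
        if any(a < 0 for a in self.harmonic_amps) or len(self.harmonic_amps) != 3:
            raise ValueError("harmonic_amps must be 3 non-negative values")
        if self.tremor_burst_duration <= 0 or self.adl_level < 0:
            raise ValueError("invalid burst duration or ADL level")


def _lowpass_noise(rng, n, fs, cutoff, rms):
    if rms <= 0:
        return np.zeros(n)
    sos = signal.butter(4, cutoff, btype="lowpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    s = x.std()
    return x * (rms / s) if s > 0 else x


def _bandpass_noise(rng, n, fs, lo, hi, rms):
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    s = x.std()
    return x * (rms / s) if s > 0 else x


def _draw_bursts(rng, duration_s, coverage, mean_on, min_on=3.0, max_on=60.0):
    """Alternating off/on periods; expected on-fraction equals coverage."""
    if coverage <= 0:
        return []
    mean_off = mean_on * (1 - coverage) / max(coverage, 1e-9)
    bursts = []
    t = float(rng.exponential(mean_off)) if mean_off > 0 else 0.0
    while t < duration_s:
        on = float(np.clip(rng.exponential(mean_on), min_on, max_on))
        end = min(t + on, duration_s)
        if end - t >= min_on / 2:
            bursts.append((t, end))
        t = end + float(rng.exponential(mean_off)) if mean_off > 0 else end
    return bursts


def gen_recording(
    profile: SubjectProfile,
    duration_s: float,
    seed: int,
    hand: str = "left",
) -> tuple:
    """Simulate one wrist recording; returns (recording, tremor intervals).

    The recording is at 100 Hz in g; the interval set holds the exact
    tremor-burst extents.  Deterministic per seed.
    """
    if duration_s < 60:
        raise ValueError("duration must be at least 60 s")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * _RAW_FS))
    t = np.arange(n) / _RAW_FS
    sig = np.zeros((n, 3))

    # gravity with slow orientation drift (all energy below 0.3 Hz)
    base = np.array([0.1, -0.2, 0.97])
    for ax in range(3):
        drift = 0.0
        for f in (0.02, 0.05, 0.09):
            drift = drift + 0.03 * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        sig[:, ax] += base[ax] + drift

    # background ADL motion, energy below 3 Hz
    for ax in range(3):
        sig[:, ax] += _lowpass_noise(rng, n, _RAW_FS, 3.0, profile.adl_level)

    # broadband 3-9 Hz confounder bursts (no harmonic comb structure)
    conf_amp = 0.4 * profile.harmonic_amps[0]
    for s, e in _draw_bursts(
        rng, duration_s, profile.confounder_coverage, mean_on=5.0, min_on=2.0, max_on=15.0
    ):
        i0, i1 = int(s * _RAW_FS), int(e * _RAW_FS)
        env = np.hanning(i1 - i0)
        for ax in range(3):
            sig[i0:i1, ax] += env * _bandpass_noise(
                rng, i1 - i0, _RAW_FS, 3.0, 9.0, conf_amp
            )

    # tremor bursts: f0 + two harmonics, Hann envelope, random phase per axis;
    # the instantaneous frequency wanders ~+-0.3 Hz and harmonic amplitudes
    # fluctuate slowly, as physiological tremor does
    bursts = _draw_bursts(
        rng,
        duration_s,
        profile.tremor_prevalence,
        mean_on=profile.tremor_burst_duration,
    )
    axis_gain = rng.uniform(0.6, 1.0, size=3)
    for s, e in bursts:
        i0, i1 = int(s * _RAW_FS), int(e * _RAW_FS)
        m = i1 - i0
        env = np.hanning(m)
        wander = _lowpass_noise(rng, m, _RAW_FS, 0.2, 0.15)
        f_inst = profile.f0 + np.clip(wander, -0.4, 0.4)
        phase = 2 * np.pi * np.cumsum(f_inst) / _RAW_FS
        for ax in range(3):
            wave = np.zeros(m)
            for k, amp in enumerate(profile.harmonic_amps, start=1):
                gain = 1.0 + np.clip(_lowpass_noise(rng, m, _RAW_FS, 0.3, 0.2), -0.6, 0.6)
                wave += amp * gain * np.sin(k * phase + rng.uniform(0, 2 * np.pi))
            sig[i0:i1, ax] += axis_gain[ax] * env * wave

    # broadband sensor/body noise floor
    sig += 0.01 * rng.standard_normal((n, 3))

    rec = AccelRecording(
        subject_id=profile.subject_id,
        hand=hand,
        sample_rate=_RAW_FS,
        samples=sig,
        units="g",
    )
    tiv = TremorIntervalSet(intervals=bursts, hand=hand)
    return rec, tiv


def gen_weak_labels(
    intervals: TremorIntervalSet,
    duration_s: float,
    entry_period_s: float = 3600.0,
    profile: SubjectProfile | None = None,
    seed: int = 0,
) -> list:
    """Derive 5-minute diary entries from the true tremor intervals.

    One entry per ``entry_period_s``, end-anchored (the diary interval is
    the 5 minutes preceding each period boundary).  The true tremor
    fraction of the interval maps onto the 3 levels; with probability
    ``label_noise`` the label shifts one level (clamped to the scale).
    """
    if duration_s < entry_period_s:
        raise ValueError("duration must cover at least one entry period")
    rng = np.random.default_rng(seed)
    noise = profile.label_noise if profile is not None else 0.0
    subject = profile.subject_id if profile is not None else "unknown"
    entries = []
    n_entries = int(duration_s // entry_period_s)
    for k in range(n_entries):
        end = (k + 1) * entry_period_s
        start = end - 300.0
        frac = intervals.overlap(start, end) / 300.0
        label = percent_to_weak_label(100.0 * frac)
        if noise > 0 and rng.random() < noise:
            i = LABEL_ORDER.index(label) + (1 if rng.random() < 0.5 else -1)
            label = LABEL_ORDER[int(np.clip(i, 0, 2))]
        entries.append(WeakLabelEntry(subject_id=subject, interval=(start, end), label=label))
    return entries


@dataclass
class Cohort:
    """A generated multi-subject dataset: recordings, truth and diaries."""

    recordings: list  # AccelRecording, one per subject-hand
    intervals: dict  # (subject_id, hand) -> TremorIntervalSet
    weak_labels: dict  # (subject_id, hand) -> list[WeakLabelEntry]
    profiles: dict  # (subject_id, hand) -> SubjectProfile
    manifest: dict


def gen_cohort(n_subjects: int, seed: int, config: dict | None = None) -> Cohort:
    """Generate a cohort with both hands per subject and diary entries.

    The default configuration records 30 minutes per hand with one diary
    entry every 5 minutes, and spreads tremor prevalence so that the
    cohort always contains a low-prevalence (<= 5 %) and a high-prevalence
    (>= 60 %) subject, mirroring the heterogeneity of real PD cohorts.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    cfg = {
        "duration_s": 1800.0,
        "entry_period_s": 300.0,
        "label_noise": 0.1,
        "f0_range": (4.3, 7.5),
        "amp_range": (0.12, 0.25),
        "adl_range": (0.03, 0.08),
        "confounder_coverage": 0.05,
    }
    cfg.update(config or {})
    rng = np.random.default_rng(seed)
    recordings, intervals, weak_labels, profiles = [], {}, {}, {}
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        f0 = float(rng.uniform(*cfg["f0_range"]))
        amp = float(rng.uniform(*cfg["amp_range"]))
        adl = float(rng.uniform(*cfg["adl_range"]))
        if i == 0:
            prev = float(rng.uniform(0.01, 0.05))  # low-prevalence subject
        elif i == 1:
            prev = float(rng.uniform(0.60, 0.80))  # high-prevalence subject
        else:
            prev = float(rng.uniform(0.10, 0.60))
        for hand in ("left", "right"):
            hand_prev = prev if hand == "right" else prev * float(rng.uniform(0.4, 1.0))
            prof = SubjectProfile(
                subject_id=sid,
                f0=f0,
                harmonic_amps=(amp, amp / 2, amp / 4),
                tremor_prevalence=min(hand_prev, 0.85),
                adl_level=adl,
                confounder_coverage=cfg["confounder_coverage"],
                label_noise=cfg["label_noise"],
            )
            sub_seed = int(rng.integers(0, 2**31 - 1))
            rec, tiv = gen_recording(prof, cfg["duration_s"], seed=sub_seed, hand=hand)
            if cfg["duration_s"] >= max(cfg["entry_period_s"], 300.0):
                entries = gen_weak_labels(
                    tiv, cfg["duration_s"], cfg["entry_period_s"], prof, seed=sub_seed + 1
                )
            else:  # recording too short for a 5-minute diary entry
                entries = []
            recordings.append(rec)
            intervals[(sid, hand)] = tiv
            weak_labels[(sid, hand)] = entries
            profiles[(sid, hand)] = prof
    manifest = {
        "seed": seed,
        "n_subjects": n_subjects,
        "config": {k: list(v) if isinstance(v, tuple) else v for k, v in cfg.items()},
        "profiles": {
            f"{sid}/{hand}": asdict(p) for (sid, hand), p in profiles.items()
        },
    }
    return Cohort(recordings, intervals, weak_labels, profiles, manifest)


def save_cohort(cohort: Cohort, out_dir) -> None:
    """Write a cohort as plain-text files (CSV recordings, JSON annotations)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in cohort.recordings:
        stem = f"{rec.subject_id}_{rec.hand}"
        save_recording(rec, out / f"{stem}.csv")
        save_intervals(cohort.intervals[(rec.subject_id, rec.hand)], out / f"{stem}_intervals.json")
        entries = cohort.weak_labels[(rec.subject_id, rec.hand)]
        (out / f"{stem}_weak_labels.json").write_text(
            json.dumps(
                [
                    {
                        "subject": e.subject_id,
                        "start": e.interval[0],
                        "end": e.interval[1],
                        "label": e.label,
                    }
                    for e in entries
                ],
                indent=1,
            )
        )
    (out / "manifest.json").write_text(json.dumps(cohort.manifest, indent=1))
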