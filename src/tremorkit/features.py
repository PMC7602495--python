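"""Hand-crafted feature sets for 3-s accelerometer windows.

Five sets are provided, all sharing the preprocessing conventions of
:mod:`tremorkit.preprocess`:

``energy``     1-d: total spectral energy in the 3-9 Hz tremor band.
``psd``        384-d: Welch one-sided PSD, 128 points per axis.
``baseline``   356-d: 16 time-domain + 27 frequency-domain statistics on
               {X, Y, Z, magnitude} x {acceleration, jerk}, plus 12
               inter-axis correlations.
``mfcc``       36-d: 12 cepstral coefficients (c1-c12) per axis, computed
               from the Hamming-tapered amplitude spectrum through a
               26-filter mel filterbank spanning 0.3-25 Hz and an
               orthonormal DCT-II.
``mfcc_tnt``   108-d: the same cepstra computed on each of the total,
               tremor and non-tremor spectra produced by the non-negative
               tremor factorization (12 x 3 spectra x 3 axes).

The cepstral pipeline mirrors the speech MFCC recipe with the mel band
rescaled to the 0-25 Hz accelerometer bandwidth; c0 is excluded, which
makes c1-c12 invariant to overall amplitude scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.fft import dct
from scipy.stats import kurtosis, skew

from .preprocess import FREQ_GRID, FS, N_FFT, N_GRID, WINDOW_SAMPLES, WindowSet, amplitude_spectrum
from .ntf import SpectrumTriple, TntSpectra

__all__ = [
    "FEATURE_DIMS",
    "FeatureMatrix",
    "energy_3_9",
    "welch_psd",
    "baseline_features",
    "baseline_feature_names",
    "mfcc_features",
    "mfcc_tnt_features",
    "mel_filterbank",
    "cepstra",
    "feature_matrix",
]

FEATURE_DIMS = {"energy": 1, "psd": 384, "baseline": 356, "mfcc": 36, "mfcc_tnt": 108}

_N_MEL = 26
_N_CEPS = 12
_LOG_FLOOR = 1e-10
_TREMOR_BAND = (FREQ_GRID >= 3.0) & (FREQ_GRID <= 9.0)


@dataclass
class FeatureMatrix:
    """Per-window feature vectors for one subject-hand recording."""

    values: np.ndarray  # (n_windows, d)
    feature_names: list
    set_id: str
    subject_id: str
    hand: str
    window_start_s: np.ndarray

    def __post_init__(self) -> None:
        d = FEATURE_DIMS[self.set_id]
        if self.values.ndim != 2 or self.values.shape[1] != d:
            raise ValueError(f"{self.set_id} features must have {d} columns")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains NaN/Inf")


def energy_3_9(window: np.ndarray) -> float:
    """Spectral energy in the 3-9 Hz tremor band, summed over axes."""
    spec = amplitude_spectrum(window)
    return float(np.sum(spec[:, _TREMOR_BAND] ** 2))


def welch_psd(window: np.ndarray) -> np.ndarray:
    """Welch one-sided PSD per axis on the shared grid, shape (3, 128)."""
    window = np.asarray(window, dtype=float)
    if window.shape != (WINDOW_SAMPLES, 3):
        raise ValueError(f"window must be ({WINDOW_SAMPLES}, 3)")
    _, psd = signal.welch(
        window, fs=FS, nperseg=75, noverlap=37, nfft=N_FFT, axis=0
    )
    return psd[:N_GRID].T


# ---------------------------------------------------------------------------
# baseline statistics


def _yule_walker2(x: np.ndarray) -> tuple:
    """Order-2 autoregressive coefficients via the Yule-Walker equations."""
    x = x - x.mean()
    v = x.var()
    if v <= 0:
        return 0.0, 0.0
    r = np.array([1.0, _acorr(x, 1), _acorr(x, 2)])
    R = np.array([[r[0], r[1]], [r[1], r[0]]])
    try:
        a = np.linalg.solve(R, r[1:])
    except np.linalg.LinAlgError:
        return 0.0, 0.0
    return float(a[0]), float(a[1])


def _acorr(x: np.ndarray, lag: int) -> float:
    d = np.dot(x, x)
    if d <= 0:
        return 0.0
    return float(np.dot(x[:-lag], x[lag:]) / d)


def _entropy(p: np.ndarray) -> float:
    s = p.sum()
    if s <= 0:
        return 0.0
    p = p[p > 0] / s
    return float(-np.sum(p * np.log(p)))


def _basic16(x: np.ndarray, is_spectrum: bool) -> list:
    """The 16 shared statistics (time domain, or on an FFT magnitude)."""
    n = len(x)
    feats = [
        x.mean(),
        x.std(),
        float(np.median(x)),
        x.max(),
        x.min(),
        float(np.mean(np.abs(x))),  # signal magnitude area (per-sample)
        float(np.mean(x**2)),  # energy
        float(np.percentile(x, 25)),
        float(np.percentile(x, 75)),
        *[float(np.quantile(x, q)) for q in (0.2, 0.4, 0.6, 0.8)],  # ECDF(4)
    ]
    if is_spectrum:
        feats.append(_entropy(x))
    else:
        hist, _ = np.histogram(np.abs(x), bins=16)
        feats.append(_entropy(hist.astype(float)))
    feats.extend(_yule_walker2(x))
    return feats


def _freq27(x: np.ndarray, fs: float) -> list:
    """27 frequency-domain statistics of one channel."""
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    feats = _basic16(spec, is_spectrum=True)
    power = spec**2
    total = power.sum()
    feats.append(float(freqs[int(np.argmax(spec))]))  # dominant frequency
    feats.append(float((freqs * power).sum() / total) if total > 0 else 0.0)  # centroid
    feats.append(float(np.mean(power)))  # spectral power
    feats.append(float(skew(spec)) if spec.std() > 0 else 0.0)
    feats.append(float(kurtosis(spec)) if spec.std() > 0 else 0.0)
    edges = np.linspace(0, fs / 2, 7)  # 6 equal bands over 0-25 Hz
    for lo, hi in zip(edges[:-1], edges[1:]):
        band = (freqs >= lo) & (freqs < hi) if hi < fs / 2 else (freqs >= lo)
        feats.append(float(power[band].sum()))
    return feats


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() <= 0 or b.std() <= 0:
        return 0.0  # correlation with a constant channel is defined as 0
    return float(np.corrcoef(a, b)[0, 1])


_BASIC16_NAMES = [
    "mean", "std", "median", "max", "min", "sma", "energy",
    "iqr25", "iqr75", "ecdf20", "ecdf40", "ecdf60", "ecdf80",
    "entropy", "ar1", "ar2",
]
_FREQ_EXTRA_NAMES = [
    "domfreq", "avgfreq", "specpower", "skew", "kurt",
    "band1", "band2", "band3", "band4", "band5", "band6",
]


def baseline_feature_names() -> list:
    names = []
    for sig in ("acc", "jerk"):
        for ch in ("x", "y", "z", "mag"):
            names += [f"{sig}_{ch}_t_{n}" for n in _BASIC16_NAMES]
            names += [f"{sig}_{ch}_f_{n}" for n in _BASIC16_NAMES + _FREQ_EXTRA_NAMES]
    for sig in ("acc", "jerk", "fft_acc", "fft_jerk"):
        for pair in ("xy", "xz", "yz"):
            names.append(f"corr_{sig}_{pair}")
    return names


def baseline_features(window: np.ndarray) -> np.ndarray:
    """The 356-dimensional conventional feature set for one window.

    16 time-domain and 27 frequency-domain statistics on each of
    {X, Y, Z, magnitude} for both acceleration and jerk (43 x 4 x 2 = 344),
    plus the inter-axis correlation of acceleration, jerk and their FFT
    magnitudes (3 pairs x 4 = 12).
    """
    window = np.asarray(window, dtype=float)
    if window.shape != (WINDOW_SAMPLES, 3):
        raise ValueError(f"window must be ({WINDOW_SAMPLES}, 3)")
    jerk = np.diff(window, axis=0) * FS
    feats: list = []
    for sig in (window, jerk):
        mag = np.linalg.norm(sig, axis=1)
        for ch in (sig[:, 0], sig[:, 1], sig[:, 2], mag):
            feats += _basic16(ch, is_spectrum=False)
            feats += _freq27(ch, FS)
    pairs = [(0, 1), (0, 2), (1, 2)]
    for sig in (window, jerk):
        for i, j in pairs:
            feats.append(_safe_corr(sig[:, i], sig[:, j]))
    for sig in (window, jerk):
        fft_mag = np.abs(np.fft.rfft(sig, axis=0))
        for i, j in pairs:
            feats.append(_safe_corr(fft_mag[:, i], fft_mag[:, j]))
    out = np.asarray(feats, dtype=float)
    assert out.shape == (356,)
    return out


# ---------------------------------------------------------------------------
# cepstral features


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(
    n_filters: int = _N_MEL, f_lo: float = 0.3, f_hi: float = 25.0
) -> np.ndarray:
    """Triangular mel-spaced filterbank on the shared 128-point grid.

    The mel scale is rescaled from the speech convention to span the
    accelerometer band (0.3-25 Hz).  Returns (n_filters, 128).
    """
    mels = np.linspace(_hz_to_mel(f_lo), _hz_to_mel(f_hi), n_filters + 2)
    edges = _mel_to_hz(mels)
    fb = np.zeros((n_filters, N_GRID))
    for i in range(n_filters):
        lo, mid, hi = edges[i], edges[i + 1], edges[i + 2]
        rise = (FREQ_GRID - lo) / (mid - lo)
        fall = (hi - FREQ_GRID) / (hi - mid)
        fb[i] = np.clip(np.minimum(rise, fall), 0.0, None)
    return fb


_FILTERBANK = mel_filterbank()


def cepstra(amp_spectrum: np.ndarray, n_ceps: int = _N_CEPS) -> np.ndarray:
    """c1..c12 of one 128-point amplitude spectrum (c0 excluded)."""
    power = np.asarray(amp_spectrum, dtype=float) ** 2
    logE = np.log(np.maximum(_FILTERBANK @ power, _LOG_FLOOR))
    c = dct(logE, type=2, norm="ortho")
    return c[1 : n_ceps + 1]


def mfcc_features(window: np.ndarray) -> np.ndarray:
    """36 MFCCs: c1-c12 per axis of the Hamming-tapered spectrum."""
    spec = amplitude_spectrum(window, taper="hamming")
    return np.concatenate([cepstra(spec[ax]) for ax in range(3)])


def mfcc_tnt_features(triple: SpectrumTriple) -> np.ndarray:
    """108 MFCCs after tremor-spectrum extraction.

    c1-c12 on each of the total, tremor and non-tremor spectra of each
    axis, ordered axis-major: (x: total, tremor, nontremor), (y: ...), ...
    """
    parts = []
    for ax in range(3):
        for spec in (triple.total[ax], triple.tremor[ax], triple.nontremor[ax]):
            parts.append(cepstra(spec))
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# batch extraction


def feature_matrix(
    ws: WindowSet, set_id: str, tnt: TntSpectra | None = None
) -> FeatureMatrix:
    """Extract one feature set for every window of a :class:`WindowSet`."""
    if set_id not in FEATURE_DIMS:
        raise ValueError(f"unknown feature set {set_id!r}")
    n = len(ws)
    if set_id == "energy":
        vals = np.array([[energy_3_9(w)] for w in ws.windows]).reshape(n, 1)
        names = ["energy_3_9"]
    elif set_id == "psd":
        vals = np.array([welch_psd(w).ravel() for w in ws.windows]).reshape(n, 384)
        names = [f"psd_{ax}_{i}" for ax in "xyz" for i in range(N_GRID)]
    elif set_id == "baseline":
        vals = np.array([baseline_features(w) for w in ws.windows]).reshape(n, 356)
        names = baseline_feature_names()
    elif set_id == "mfcc":
        vals = np.array([mfcc_features(w) for w in ws.windows]).reshape(n, 36)
        names = [f"mfcc_{ax}_c{i}" for ax in "xyz" for i in range(1, 13)]
    else:  # mfcc_tnt
        if tnt is None:
            raise ValueError("mfcc_tnt requires factorized spectra (tnt=...)")
        vals = np.array(
            [mfcc_tnt_features(tnt.triple(i)) for i in range(n)]
        ).reshape(n, 108)
        names = [
            f"mfcc_{ax}_{part}_c{i}"
            for ax in "xyz"
            for part in ("total", "tremor", "nontremor")
            for i in range(1, 13)
        ]
    return FeatureMatrix(
        values=vals,
        feature_names=names,
        set_id=set_id,
        subject_id=ws.subject_id,
        hand=ws.hand,
        window_start_s=ws.window_start_s,
    )
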