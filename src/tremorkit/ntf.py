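"""Non-negative tremor factorization (NTF).

Each window's amplitude spectrum ``S_total`` (128 points, 0-25 Hz) is
approximated as the sum of a tremor part and a non-tremor part::

    S_hat = S_tremor + S_nontremor
    S_tremor = (w_t @ T) * (w_h @ H)        (source * shape, elementwise)
    S_nontremor = w_a @ A

``T`` holds 60 "ideal" tremor source spectra -- combs of three rectified
sinc lobes at a base frequency f0 and its harmonics 2*f0 and 3*f0, with f0
stepped every 0.1 Hz over [3, 9) -- plus an all-ones row whose weight acts
as a detection threshold for the other source weights.  ``H`` (and ``A``,
identical) hold 63 narrow Hann bumps that tile the grid with 50 % overlap
and model smooth spectral envelopes.

The weights are fitted by non-negative least squares using multiplicative
(NMF-style) updates; each block update keeps the Euclidean objective
non-increasing, and the reconstruction is recomputed after every update.
After the final iteration the threshold weight zeroes all smaller source
weights; an optional per-subject personalization reshapes ``T`` by the
subject's average spectrum and restricts the surviving weights to a +-1 Hz
band around an estimated base frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks
from scipy.signal.windows import hann

from .preprocess import FREQ_GRID, N_GRID, WindowSet

__all__ = [
    "N_TREMOR_BASES",
    "N_SHAPE_BASES",
    "TremorDictionary",
    "FactorizationWeights",
    "SpectrumTriple",
    "build_dictionary",
    "factorize",
    "factorize_batch",
    "personalize",
    "constrain_to_f0",
    "estimate_base_frequency",
    "split_spectra",
    "tremor_energy",
    "analyze_windows",
    "TntSpectra",
]

#: number of ideal tremor source spectra (base frequencies 3.0 .. 8.9 Hz)
N_TREMOR_BASES = 60
#: number of Hann shape/non-tremor bases
N_SHAPE_BASES = 63
#: spectral half-width of a sinc lobe, Hz (resolution of a 3-s window)
_SINC_WIDTH_HZ = 1.0 / 3.0
#: relative amplitudes of the base frequency and its two harmonics
_HARMONIC_AMPS = (1.0, 0.5, 0.25)
#: denominator floor for the multiplicative updates
_EPS = 1e-12


@dataclass
class TremorDictionary:
    """Fixed NTF dictionaries and optional personalization state."""

    T: np.ndarray  # (61, 128): 60 tremor rows + all-ones threshold row
    H: np.ndarray  # (63, 128) Hann shape bases
    A: np.ndarray  # (63, 128) non-tremor bases (equal to H)
    base_freqs: np.ndarray  # (60,) Hz
    personalized: bool = False
    f0: float | None = None


@dataclass
class FactorizationWeights:
    """Non-negative weight vectors for one spectrum plus the fit trace."""

    wt: np.ndarray  # (61,) source weights, last entry is the threshold weight
    wh: np.ndarray  # (63,) shape weights
    wa: np.ndarray  # (63,) non-tremor weights
    n_iter: int
    objective_trace: np.ndarray  # per-iteration ||S - S_hat||^2


@dataclass
class SpectrumTriple:
    """Total / tremor / non-tremor amplitude spectra, (3 axes, 128 points)."""

    total: np.ndarray
    tremor: np.ndarray
    nontremor: np.ndarray


def build_dictionary(grid: np.ndarray = FREQ_GRID) -> TremorDictionary:
    """Construct the fixed dictionaries on the shared 128-point grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.shape != (N_GRID,):
        raise ValueError(f"grid must have {N_GRID} points")
    base_freqs = 3.0 + 0.1 * np.arange(N_TREMOR_BASES)
    T = np.zeros((N_TREMOR_BASES + 1, N_GRID))
    for i, f0 in enumerate(base_freqs):
        row = np.zeros(N_GRID)
        for k, amp in enumerate(_HARMONIC_AMPS, start=1):
            row += amp * np.abs(np.sinc((grid - k * f0) / _SINC_WIDTH_HZ))
        T[i] = row
    T[-1] = 1.0  # all-ones row; its weight thresholds the source weights

    bump = hann(5, sym=True)  # [0, .5, 1, .5, 0]
    centers = np.arange(2, N_GRID - 1, 2)  # 2, 4, ..., 126 -> 63 bases
    H = np.zeros((len(centers), N_GRID))
    for j, c in enumerate(centers):
        lo, hi = c - 2, c + 3
        H[j, max(lo, 0) : min(hi, N_GRID)] = bump[max(0, -lo) : 5 - max(0, hi - N_GRID)]
    assert H.shape[0] == N_SHAPE_BASES
    return TremorDictionary(T=T, H=H, A=H.copy(), base_freqs=base_freqs)


def _validate_spectrum(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.shape[-1] != N_GRID:
        raise ValueError(f"spectrum must have {N_GRID} points")
    if (S < 0).any():
        raise ValueError("input spectrum must be non-negative")
    return S


def factorize_batch(
    S: np.ndarray, dic: TremorDictionary, n_iter: int = 100
) -> FactorizationWeights:
    """Fit NTF weights for a batch of spectra, shape (n, 128), in one pass.

    Vectorized variant of :func:`factorize`; every spectrum is fitted
    independently but the multiplicative updates run as batched matrix
    products.  Returns stacked weights of shapes (n, 61)/(n, 63)/(n, 63)
    and an objective trace of shape (n_iter, n).
    """
    S = np.atleast_2d(_validate_spectrum(S))
    n = S.shape[0]
    T, H, A = dic.T, dic.H, dic.A
    wt = np.ones((n, T.shape[0]))
    wh = np.ones((n, H.shape[0]))
    wa = np.ones((n, A.shape[0]))
    trace = np.empty((n_iter, n))
    for it in range(n_iter):
        source = wt @ T
        shape = wh @ H
        s_hat = source * shape + wa @ A
        wt *= ((shape * S) @ T.T) / np.maximum((shape * s_hat) @ T.T, _EPS)

        source = wt @ T
        s_hat = source * shape + wa @ A
        wh *= ((source * S) @ H.T) / np.maximum((source * s_hat) @ H.T, _EPS)

        shape = wh @ H
        s_hat = source * shape + wa @ A
        wa *= (S @ A.T) / np.maximum(s_hat @ A.T, _EPS)

        s_hat = source * shape + wa @ A
        trace[it] = np.sum((S - s_hat) ** 2, axis=1)
    # the all-ones row's weight thresholds the tremor source weights
    thr = wt[:, -1:]
    wt[:, :-1] = np.where(wt[:, :-1] < thr, 0.0, wt[:, :-1])
    return FactorizationWeights(wt=wt, wh=wh, wa=wa, n_iter=n_iter, objective_trace=trace)


def factorize(
    S_total: np.ndarray, dic: TremorDictionary, n_iter: int = 100
) -> FactorizationWeights:
    """Fit the three non-negative weight vectors for one spectrum.

    Runs ``n_iter`` rounds of the three multiplicative updates (source,
    shape, non-tremor; reconstruction recomputed after each), then applies
    the threshold rule: every source weight below the all-ones row's weight
    is set to zero.
    """
    S = _validate_spectrum(np.asarray(S_total))
    if S.ndim != 1:
        raise ValueError("factorize expects a single 128-point spectrum")
    res = factorize_batch(S[None, :], dic, n_iter=n_iter)
    return FactorizationWeights(
        wt=res.wt[0],
        wh=res.wh[0],
        wa=res.wa[0],
        n_iter=n_iter,
        objective_trace=res.objective_trace[:, 0],
    )


def personalize(dic: TremorDictionary, avg_spectrum: np.ndarray) -> TremorDictionary:
    """Adapt the dictionary to one subject's average power spectrum.

    The 60 tremor rows are multiplied elementwise by the max-normalized
    average spectrum shape, and the base tremor frequency ``f0`` is set to
    the highest local maximum of the average spectrum within 4-8 Hz.
    Degenerate inputs (all-zero or without a strict local maximum in the
    band) leave the dictionary unpersonalized, with a warning.
    """
    avg = _validate_spectrum(np.asarray(avg_spectrum))
    if avg.ndim != 1:
        raise ValueError("avg_spectrum must be a single 128-point spectrum")
    if not avg.max() > 0:
        warnings.warn("all-zero average spectrum; personalization refused")
        return replace(dic, personalized=False, f0=None)
    peaks, _ = find_peaks(avg)
    band = peaks[(FREQ_GRID[peaks] >= 4.0) & (FREQ_GRID[peaks] <= 8.0)]
    if band.size == 0:
        warnings.warn("no spectral peak in 4-8 Hz; personalization refused")
        return replace(dic, personalized=False, f0=None)
    f0 = float(FREQ_GRID[band[np.argmax(avg[band])]])
    shape = avg / avg.max()
    T = dic.T.copy()
    T[:-1] *= shape[None, :]  # ones (threshold) row untouched
    return replace(dic, T=T, personalized=True, f0=f0)


def constrain_to_f0(
    w: FactorizationWeights, dic: TremorDictionary
) -> FactorizationWeights:
    """Keep only the 3 largest source weights within +-1 Hz of the personal f0.

    All other tremor source weights (including every one outside the band)
    are zeroed; the threshold weight is untouched.  Ties between equal
    weights break toward the lower base frequency.  Applied once, after
    fitting and thresholding.
    """
    if not dic.personalized or dic.f0 is None:
        raise ValueError("constrain_to_f0 requires a personalized dictionary")
    wt = np.array(w.wt, dtype=float)
    in_band = np.abs(dic.base_freqs - dic.f0) <= 1.0 + 1e-12
    keep = np.zeros(len(dic.base_freqs), dtype=bool)
    band_idx = np.flatnonzero(in_band)
    if band_idx.size:
        # stable argsort on negated values -> equal weights keep lower f0 first
        order = band_idx[np.argsort(-wt[band_idx], kind="stable")]
        keep[order[:3]] = True
    wt[:-1] = np.where(keep, wt[:-1], 0.0)
    return replace(w, wt=wt)


def estimate_base_frequency(
    w: FactorizationWeights, dic: TremorDictionary
) -> float | None:
    """Base-frequency estimate from one window's fitted factorization.

    The source and shape factors are only identified up to a shared scale,
    so raw source weights are not comparable across rows; each surviving
    row is instead weighted by the energy it actually contributes to the
    extracted tremor spectrum, ``||w_i * t_i(f) * S_shape||^2``.  With a
    personalized dictionary the average is restricted to the three largest
    contributors within +-1 Hz of the personal f0; returns None when no
    tremor weight survives.
    """
    shape = w.wh @ dic.H
    e = np.sum((w.wt[:-1, None] * dic.T[:-1] * shape[None, :]) ** 2, axis=1)
    if dic.personalized and dic.f0 is not None:
        e = np.where(np.abs(dic.base_freqs - dic.f0) <= 1.0 + 1e-12, e, 0.0)
        top = np.argsort(-e)[:3]
        mask = np.zeros_like(e, dtype=bool)
        mask[top] = True
        e = np.where(mask, e, 0.0)
    if not e.sum() > 0:
        return None
    return float(np.sum(e * dic.base_freqs) / e.sum())


def split_spectra(
    w: FactorizationWeights, dic: TremorDictionary, S_total: np.ndarray
) -> SpectrumTriple:
    """Reconstruct the tremor / non-tremor spectra from fitted weights.

    Accepts a single spectrum (128,) with one weight set, or stacked
    per-axis spectra (3, 128) with per-axis weight matrices.
    """
    S = _validate_spectrum(np.asarray(S_total))
    wt = np.atleast_2d(w.wt)
    wh = np.atleast_2d(w.wh)
    wa = np.atleast_2d(w.wa)
    tremor = (wt @ dic.T) * (wh @ dic.H)
    nontremor = wa @ dic.A
    if S.ndim == 1:
        tremor, nontremor = tremor[0], nontremor[0]
    elif tremor.shape[0] != S.shape[0]:
        raise ValueError("weight rows do not match number of spectra")
    return SpectrumTriple(total=S, tremor=tremor, nontremor=nontremor)


def tremor_energy(triple: SpectrumTriple) -> float:
    """Unsupervised tremor-energy score: summed squared tremor amplitudes."""
    return float(np.sum(np.asarray(triple.tremor) ** 2))


@dataclass
class TntSpectra:
    """Factorized spectra for every window of one subject-hand recording."""

    total: np.ndarray  # (n, 3, 128)
    tremor: np.ndarray  # (n, 3, 128)
    nontremor: np.ndarray  # (n, 3, 128)
    energy: np.ndarray  # (n,) tremor-energy score per window
    dictionary: TremorDictionary

    def triple(self, i: int) -> SpectrumTriple:
        return SpectrumTriple(
            total=self.total[i], tremor=self.tremor[i], nontremor=self.nontremor[i]
        )

    def stacked(self) -> np.ndarray:
        """(n, 9, 128) input for the spectral CNN: 3 spectra x 3 axes."""
        return np.concatenate([self.total, self.tremor, self.nontremor], axis=1)


def analyze_windows(
    ws: WindowSet,
    personalize_dict: bool = True,
    n_iter: int = 100,
    dic: TremorDictionary | None = None,
) -> TntSpectra:
    """Run the full NTF pipeline over a :class:`WindowSet`.

    Computes amplitude spectra, optionally personalizes the dictionary on
    the subject's average power spectrum (and then constrains the surviving
    source weights to +-1 Hz around the estimated f0), factorizes every
    axis of every window, and returns the per-window spectrum triples and
    tremor-energy scores.
    """
    if dic is None:
        dic = build_dictionary()
    spectra = ws.spectra()  # (n, 3, 128)
    n = spectra.shape[0]
    if n == 0:
        z = np.zeros((0, 3, N_GRID))
        return TntSpectra(z, z.copy(), z.copy(), np.zeros(0), dic)
    if personalize_dict:
        avg_power = np.mean(spectra**2, axis=(0, 1))
        dic = personalize(dic, avg_power)
    flat = spectra.reshape(n * 3, N_GRID)
    w = factorize_batch(flat, dic, n_iter=n_iter)
    if dic.personalized:
        w = _constrain_batch(w, dic)
    tremor = ((w.wt @ dic.T) * (w.wh @ dic.H)).reshape(n, 3, N_GRID)
    nontremor = (w.wa @ dic.A).reshape(n, 3, N_GRID)
    energy = np.sum(tremor**2, axis=(1, 2))
    return TntSpectra(
        total=spectra, tremor=tremor, nontremor=nontremor, energy=energy, dictionary=dic
    )


def _constrain_batch(
    w: FactorizationWeights, dic: TremorDictionary
) -> FactorizationWeights:
    """Vectorized constrain_to_f0 over stacked weight rows."""
    wt = np.array(w.wt, dtype=float)
    in_band = np.abs(dic.base_freqs - dic.f0) <= 1.0 + 1e-12
    vals = np.where(in_band[None, :], wt[:, :-1], -np.inf)
    order = np.argsort(-vals, axis=1, kind="stable")[:, :3]
    keep = np.zeros_like(wt[:, :-1], dtype=bool)
    np.put_along_axis(keep, order, np.take_along_axis(vals, order, 1) > -np.inf, 1)
    wt[:, :-1] = np.where(keep, wt[:, :-1], 0.0)
    return replace(w, wt=wt)
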