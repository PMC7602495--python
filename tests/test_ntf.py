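"""Tremor-factorization dictionaries, updates, thresholding, personalization."""

import numpy as np
import pytest

from tremorkit import ntf
from tremorkit.preprocess import FREQ_GRID

from conftest import make_sine_window


@pytest.fixture(scope="module")
def dic():
    return ntf.build_dictionary()


def _tremor_spectrum(dic, row, scale=0.7, shape_rows=slice(8, 20)):
    """A spectrum exactly consistent with the dictionary's tremor model."""
    wh = np.zeros(dic.H.shape[0])
    wh[shape_rows] = 1.0
    return scale * dic.T[row] * (wh @ dic.H)


class TestDictionary:
    def test_tremor_row_and_threshold_row_counts(self, dic):
        assert dic.T.shape == (61, 128)
        assert np.all(dic.T[-1] == 1.0)
        assert len(dic.base_freqs) == 60

    def test_hann_base_count_and_positivity(self, dic):
        assert dic.H.shape == (63, 128)
        assert np.all(dic.H >= 0)
        assert np.all(dic.H.sum(axis=1) > 0)
        np.testing.assert_array_equal(dic.A, dic.H)

    def test_base_frequency_grid(self, dic):
        np.testing.assert_allclose(np.diff(dic.base_freqs), 0.1)
        assert dic.base_freqs[0] == 3.0
        assert dic.base_freqs[-1] == pytest.approx(8.9)

    def test_tremor_row_peaks_at_its_base_frequency(self, dic):
        row = dic.T[20]  # f0 = 5.0 Hz
        peak = FREQ_GRID[np.argmax(row)]
        assert abs(peak - 5.0) <= FREQ_GRID[1]

    def test_harmonic_lobes_present(self, dic):
        row = dic.T[20]
        for k, f in enumerate((5.0, 10.0, 15.0), start=1):
            bin_ = np.argmin(np.abs(FREQ_GRID - f))
            assert row[bin_] > 0.2 / k

    def test_wrong_grid_rejected(self):
        with pytest.raises(ValueError):
            ntf.build_dictionary(np.linspace(0, 25, 64))


class TestFactorize:
    def test_zero_spectrum_gives_zero_weights(self, dic):
        w = ntf.factorize(np.zeros(128), dic)
        assert np.all(w.wt[:-1] == 0)
        trip = ntf.split_spectra(w, dic, np.zeros(128))
        np.testing.assert_allclose(trip.tremor + trip.nontremor, 0, atol=1e-12)

    def test_negative_spectrum_rejected(self, dic):
        with pytest.raises(ValueError):
            ntf.factorize(-np.ones(128), dic)

    def test_objective_nonincreasing_on_random_spectra(self, dic, rng):
        S = rng.random((200, 128))
        w = ntf.factorize_batch(S, dic, n_iter=100)
        tr = w.objective_trace
        viol = np.diff(tr, axis=0) > 1e-9 * tr[:-1]
        assert not viol.any()

    def test_weights_stay_nonnegative(self, dic, rng):
        S = rng.random((20, 128)) * 5
        w = ntf.factorize_batch(S, dic)
        assert np.all(w.wt >= 0) and np.all(w.wh >= 0) and np.all(w.wa >= 0)

    def test_dictionary_consistent_tremor_recovered(self, dic):
        S = _tremor_spectrum(dic, row=20)
        w = ntf.factorize(S, dic, n_iter=100)
        trip = ntf.split_spectra(w, dic, S)
        e_t = np.sum(trip.tremor**2)
        e_n = np.sum(trip.nontremor**2)
        assert e_t / (e_t + e_n) >= 0.90

    def test_threshold_rule_idempotent(self, dic, rng):
        S = rng.random(128)
        w = ntf.factorize(S, dic)
        thr = w.wt[-1]
        assert np.all((w.wt[:-1] == 0) | (w.wt[:-1] >= thr))

    def test_batch_matches_single(self, dic, rng):
        S = rng.random((3, 128))
        batch = ntf.factorize_batch(S, dic, n_iter=50)
        for i in range(3):
            single = ntf.factorize(S[i], dic, n_iter=50)
            np.testing.assert_allclose(single.wt, batch.wt[i], rtol=1e-12)


class TestPersonalize:
    def test_peak_detected_in_4_8_band(self, dic):
        avg = np.exp(-0.5 * ((FREQ_GRID - 6.0) / 0.3) ** 2)
        out = ntf.personalize(dic, avg)
        assert out.personalized
        assert out.f0 == pytest.approx(6.0, abs=FREQ_GRID[1])

    def test_peak_outside_search_band_ignored(self, dic):
        # strongest peak at 3.2 Hz (inside the dictionary range but outside
        # the 4-8 Hz search band); a weaker peak at 5 Hz must win
        avg = 2.0 * np.exp(-0.5 * ((FREQ_GRID - 3.2) / 0.2) ** 2)
        avg += 1.0 * np.exp(-0.5 * ((FREQ_GRID - 5.0) / 0.2) ** 2)
        out = ntf.personalize(dic, avg)
        assert out.f0 == pytest.approx(5.0, abs=FREQ_GRID[1])

    def test_flat_spectrum_refused(self, dic):
        with pytest.warns(UserWarning):
            out = ntf.personalize(dic, np.ones(128))
        assert not out.personalized

    def test_zero_spectrum_refused(self, dic):
        with pytest.warns(UserWarning):
            out = ntf.personalize(dic, np.zeros(128))
        assert not out.personalized

    def test_ones_row_untouched(self, dic):
        avg = np.exp(-0.5 * ((FREQ_GRID - 6.0) / 0.3) ** 2)
        out = ntf.personalize(dic, avg)
        np.testing.assert_array_equal(out.T[-1], 1.0)


class TestConstrainToF0:
    def _weights(self, dic, freq_vals):
        wt = np.zeros(61)
        for f, v in freq_vals.items():
            wt[np.argmin(np.abs(dic.base_freqs - f))] = v
        return ntf.FactorizationWeights(
            wt=wt, wh=np.zeros(63), wa=np.zeros(63), n_iter=0,
            objective_trace=np.zeros(0),
        )

    def _personalized(self, dic, f0):
        avg = np.exp(-0.5 * ((FREQ_GRID - f0) / 0.3) ** 2)
        return ntf.personalize(dic, avg)

    def test_three_largest_in_band_kept(self, dic):
        pdic = self._personalized(dic, 5.0)
        w = self._weights(dic, {4.2: 1, 4.9: 2, 5.0: 5, 5.1: 3, 6.5: 9})
        out = ntf.constrain_to_f0(w, pdic)
        kept = dic.base_freqs[out.wt[:-1] > 0]
        assert sorted(np.round(kept, 1)) == [4.9, 5.0, 5.1]

    def test_all_zero_unchanged(self, dic):
        pdic = self._personalized(dic, 5.0)
        w = self._weights(dic, {})
        out = ntf.constrain_to_f0(w, pdic)
        assert np.all(out.wt == 0)

    def test_idempotent(self, dic):
        pdic = self._personalized(dic, 5.0)
        w = self._weights(dic, {4.5: 1, 4.9: 2, 5.0: 5, 5.1: 3, 5.3: 4})
        once = ntf.constrain_to_f0(w, pdic)
        twice = ntf.constrain_to_f0(once, pdic)
        np.testing.assert_array_equal(once.wt, twice.wt)

    def test_requires_personalized_dictionary(self, dic):
        w = self._weights(dic, {5.0: 1})
        with pytest.raises(ValueError):
            ntf.constrain_to_f0(w, dic)


class TestSplitAndEnergy:
    def test_triple_identity(self, dic, rng):
        S = rng.random(128)
        w = ntf.factorize(S, dic, n_iter=50)
        trip = ntf.split_spectra(w, dic, S)
        recon = (w.wt @ dic.T) * (w.wh @ dic.H) + w.wa @ dic.A
        np.testing.assert_allclose(trip.tremor + trip.nontremor, recon, rtol=1e-10)

    def test_energy_quadratic(self, dic):
        trip = ntf.SpectrumTriple(
            total=np.ones((3, 128)), tremor=np.ones((3, 128)),
            nontremor=np.zeros((3, 128)),
        )
        e1 = ntf.tremor_energy(trip)
        trip2 = ntf.SpectrumTriple(
            total=trip.total, tremor=2 * trip.tremor, nontremor=trip.nontremor
        )
        assert ntf.tremor_energy(trip2) == pytest.approx(4 * e1)

    def test_adl_only_spectrum_low_tremor_fraction(self, dic, rng):
        # background-motion spectrum: energy only below 3 Hz
        S = np.where(FREQ_GRID < 3.0, 1.0 + rng.random(128), 0.0)
        S[FREQ_GRID >= 3.0] = 0.0
        w = ntf.factorize(S, dic)
        trip = ntf.split_spectra(w, dic, S)
        frac = np.sum(trip.tremor**2) / max(np.sum(trip.tremor**2) + np.sum(trip.nontremor**2), 1e-30)
        assert frac < 0.10

    def test_tremor_windows_outrank_adl_windows(self, dic, rng):
        # pure-tremor vs pure-background windows: the unsupervised energy
        # score must rank tremor first in >= 95 % of random pairs
        from tremorkit.preprocess import amplitude_spectrum

        t = np.arange(150) / 50.0
        scores = {"tremor": [], "adl": []}
        for i in range(20):
            f0 = rng.uniform(4, 8)
            w_t = np.stack(
                [np.sin(2 * np.pi * f0 * t + rng.uniform(0, 6)) * 0.3] * 3, axis=1
            ) + 0.01 * rng.standard_normal((150, 3))
            w_a = np.stack(
                [np.sin(2 * np.pi * rng.uniform(0.5, 2.0) * t) * 0.3] * 3, axis=1
            ) + 0.01 * rng.standard_normal((150, 3))
            for kind, win in (("tremor", w_t), ("adl", w_a)):
                S = amplitude_spectrum(win)
                res = ntf.factorize_batch(S, dic)
                trip = ntf.split_spectra(res, dic, S)
                scores[kind].append(np.sum(np.asarray(trip.tremor) ** 2))
        wins = sum(
            te > ae for te in scores["tremor"] for ae in scores["adl"]
        )
        assert wins / (len(scores["tremor"]) * len(scores["adl"])) >= 0.95


class TestAnalyzeWindows:
    def test_pipeline_on_synthetic_windows(self, rng):
        from tremorkit.preprocess import WindowSet

        wins = 0.05 * rng.standard_normal((12, 150, 3))
        t = np.arange(150) / 50.0
        for i in range(6):
            wins[i] += 0.4 * np.sin(2 * np.pi * 6.0 * t)[:, None]
        ws = WindowSet(
            windows=wins, window_start_s=np.arange(12.0), subject_id="s", hand="left"
        )
        res = ntf.analyze_windows(ws)
        assert res.total.shape == (12, 3, 128)
        assert res.stacked().shape == (12, 9, 128)
        # tremor windows carry more factorized tremor energy
        assert res.energy[:6].min() > res.energy[6:].max()
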