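"""Ingest, resampling, filtering, windowing and the window-label rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tremorkit import preprocess as pp
from tremorkit.synth import SubjectProfile, gen_recording

from conftest import make_sine_window


def _recording(samples, rate=50.0, **kw):
    return pp.AccelRecording(
        subject_id=kw.get("subject_id", "s"),
        hand=kw.get("hand", "left"),
        sample_rate=rate,
        samples=samples,
    )


class TestLoadRecording:
    def test_uniform_100hz_csv(self, tmp_path):
        t = np.arange(300) / 100.0
        path = tmp_path / "rec.csv"
        path.write_text(
            "t,x,y,z\n" + "\n".join(f"{ti},{0.1},{0.2},{1.0}" for ti in t)
        )
        rec = pp.load_recording(path)
        assert rec.sample_rate == pytest.approx(100.0)
        assert rec.n_samples == 300

    def test_nan_row_rejected_with_row_number(self, tmp_path):
        path = tmp_path / "rec.csv"
        path.write_text("t,x,y,z\n0.0,1,2,3\n0.01,,2,3\n0.02,1,2,3\n")
        with pytest.raises(ValueError, match="row 1"):
            pp.load_recording(path)

    def test_non_monotonic_time_rejected(self, tmp_path):
        path = tmp_path / "rec.csv"
        path.write_text("t,x,y,z\n0.0,1,2,3\n0.02,1,2,3\n0.01,1,2,3\n")
        with pytest.raises(ValueError, match="non-monotonic"):
            pp.load_recording(path)

    def test_writer_output_round_trips(self, tmp_path):
        prof = SubjectProfile(subject_id="p1", tremor_prevalence=0.4)
        rec, _ = gen_recording(prof, duration_s=60, seed=3)
        pp.save_recording(rec, tmp_path / "p1.csv")
        back = pp.load_recording(tmp_path / "p1.csv")
        np.testing.assert_array_equal(back.samples, rec.samples)
        assert back.subject_id == "p1"
        assert back.sample_rate == pytest.approx(rec.sample_rate, rel=1e-9)


class TestResample:
    def test_50hz_identity(self):
        rec = _recording(np.random.default_rng(0).normal(size=(200, 3)))
        assert pp.resample_to_50hz(rec) is rec

    def test_100hz_halves_sample_count(self):
        rec = _recording(np.zeros((300, 3)), rate=100.0)
        out = pp.resample_to_50hz(rec)
        assert out.sample_rate == 50.0
        assert out.n_samples == 150

    def test_below_50hz_rejected(self):
        rec = _recording(np.zeros((100, 3)), rate=25.0)
        with pytest.raises(ValueError):
            pp.resample_to_50hz(rec)

    def test_tone_preserved_through_decimation(self):
        # 5 Hz sine sampled at 100 Hz: after downsampling the FFT peak
        # stays at 5 Hz and the amplitude is preserved within 2 %
        t = np.arange(2000) / 100.0
        sig = np.stack([np.sin(2 * np.pi * 5 * t)] * 3, axis=1)
        out = pp.resample_to_50hz(_recording(sig, rate=100.0))
        spec = np.abs(np.fft.rfft(out.samples[:, 0]))
        freqs = np.fft.rfftfreq(out.n_samples, 1 / 50.0)
        assert freqs[np.argmax(spec)] == pytest.approx(5.0, abs=0.06)
        amp = 2 * spec.max() / out.n_samples
        assert amp == pytest.approx(1.0, rel=0.02)


class TestHighpass:
    def test_dc_offset_removed(self):
        rec = _recording(np.ones((500, 3)))
        out = pp.highpass_gravity(rec)
        assert np.abs(out.samples[100:-100]).max() < 1e-6

    def test_passband_tone_unattenuated(self):
        t = np.arange(1000) / 50.0
        rec = _recording(np.stack([np.sin(2 * np.pi * 5 * t)] * 3, axis=1))
        out = pp.highpass_gravity(rec)
        amp = np.sqrt(2) * out.samples[200:-200, 0].std()  # sine amplitude via RMS
        assert amp == pytest.approx(1.0, rel=0.01)

    def test_deep_stopband_attenuation(self):
        # |H| for a 3rd-order Butterworth at 0.05 Hz (cutoff 0.3 Hz) is
        # 1/sqrt(1+(0.3/0.05)^6) per pass ~ -46.7 dB; doubled by the
        # zero-phase forward-backward pass
        t = np.arange(30000) / 50.0
        rec = _recording(np.stack([np.sin(2 * np.pi * 0.05 * t)] * 3, axis=1))
        out = pp.highpass_gravity(rec)
        mid = out.samples[10000:20000, 0]
        atten_db = -20 * np.log10(np.abs(mid).max())
        assert atten_db >= 40.0

    def test_linearity(self, rng):
        x = rng.normal(size=(400, 3))
        a = 3.7
        out1 = pp.highpass_gravity(_recording(a * x)).samples
        out2 = a * pp.highpass_gravity(_recording(x)).samples
        np.testing.assert_allclose(out1, out2, rtol=1e-10, atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="short"):
            pp.highpass_gravity(_recording(np.zeros((100, 3))))


class TestWindows:
    def test_10s_recording_gives_8_windows(self):
        ws = pp.make_windows(_recording(np.zeros((500, 3))))
        assert len(ws) == 8
        assert ws.windows.shape == (8, 150, 3)

    def test_too_short_gives_empty_set(self):
        ws = pp.make_windows(_recording(np.zeros((145, 3))))
        assert len(ws) == 0

    @settings(deadline=None, max_examples=30)
    @given(st.integers(min_value=1, max_value=3000))
    def test_window_count_formula(self, n_samples):
        ws = pp.make_windows(_recording(np.zeros((n_samples, 3))))
        # brute-force enumeration of valid window starts
        expected = sum(
            1 for s in range(0, n_samples, 50) if s + 150 <= n_samples
        )
        assert len(ws) == expected

    def test_hop_is_one_second(self):
        ws = pp.make_windows(_recording(np.zeros((400, 3))))
        np.testing.assert_allclose(np.diff(ws.window_start_s), 1.0)


class TestLabelRule:
    def _ws(self, n=5):
        return pp.make_windows(_recording(np.zeros((150 + 50 * (n - 1), 3))))

    def test_window_inside_interval_is_tremor(self):
        ws = pp.label_windows(self._ws(), pp.TremorIntervalSet([(0.0, 100.0)]))
        assert ws.label.tolist() == [1] * 5

    def test_majority_overlap_threshold(self):
        # window [0, 3): overlap 1.6 s -> tremor; 1.4 s -> not; 1.5 s -> not
        for ov, want in [(1.6, 1), (1.4, 0), (1.5, 0)]:
            ws = pp.label_windows(self._ws(1), pp.TremorIntervalSet([(0.0, ov)]))
            assert ws.label[0] == want, ov

    def test_split_intervals_accumulate_overlap(self):
        # two disjoint events overlapping one window by 0.9 s each
        tiv = pp.TremorIntervalSet([(0.0, 0.9), (1.5, 2.4)])
        ws = pp.label_windows(self._ws(1), tiv)
        assert ws.label[0] == 1

    def test_empty_interval_set(self):
        ws = pp.label_windows(self._ws(), pp.TremorIntervalSet([]))
        assert ws.label.sum() == 0

    def test_hand_mismatch_rejected(self):
        with pytest.raises(ValueError, match="hand"):
            pp.label_windows(self._ws(), pp.TremorIntervalSet([(0, 1)], hand="right"))

    @settings(deadline=None, max_examples=25)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 20, allow_nan=False), st.floats(0.1, 5, allow_nan=False)
            ),
            max_size=5,
        )
    )
    def test_label_matches_brute_force_overlap(self, raw):
        intervals = [(s, s + d) for s, d in raw]
        tiv = pp.TremorIntervalSet(intervals or [(100.0, 101.0)])
        ws = pp.label_windows(self._ws(8), tiv)
        for i, start in enumerate(ws.window_start_s):
            grid = start + np.linspace(0, 3, 3001)[:-1] + 3 / 6002
            inside = np.zeros(len(grid), dtype=bool)
            for s, e in tiv.intervals:
                inside |= (grid >= s) & (grid < e)
            frac = inside.mean()
            if abs(frac - 0.5) > 1e-3:  # away from the tie boundary
                assert ws.label[i] == int(frac > 0.5)


class TestAmplitudeSpectrum:
    def test_zero_window_zero_spectrum(self):
        spec = pp.amplitude_spectrum(np.zeros((150, 3)))
        assert spec.shape == (3, 128)
        assert np.all(spec == 0)

    def test_tone_lands_on_nearest_bin(self):
        spec = pp.amplitude_spectrum(make_sine_window(5.0))
        peak = pp.FREQ_GRID[np.argmax(spec[0])]
        assert abs(peak - 5.0) <= pp.FS / pp.N_FFT

    def test_grid_covers_0_to_25(self):
        assert pp.FREQ_GRID[0] == 0.0
        assert pp.FREQ_GRID[-1] < 25.0
        assert len(pp.FREQ_GRID) == 128
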