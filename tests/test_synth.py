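"""Generator contracts: determinism, spectral placement, labels, cohorts."""

import numpy as np
import pytest

import tremorkit as tk
from tremorkit import preprocess as pp
from tremorkit.evaluate import percent_to_weak_label
from tremorkit.synth import SubjectProfile, gen_cohort, gen_recording, gen_weak_labels


@pytest.fixture(scope="module")
def profile():
    return SubjectProfile(subject_id="p", f0=5.5, tremor_prevalence=0.4)


class TestGenRecording:
    def test_deterministic_per_seed(self, profile):
        r1, i1 = gen_recording(profile, 60, seed=9)
        r2, i2 = gen_recording(profile, 60, seed=9)
        np.testing.assert_array_equal(r1.samples, r2.samples)
        assert i1.intervals == i2.intervals

    def test_zero_prevalence_no_bursts(self):
        prof = SubjectProfile(subject_id="p", tremor_prevalence=0.0)
        rec, tiv = gen_recording(prof, 120, seed=0)
        assert tiv.intervals == []

    def test_rate_and_units(self, profile):
        rec, _ = gen_recording(profile, 60, seed=1)
        assert rec.sample_rate == 100.0
        assert rec.n_samples == 6000

    def test_burst_spectral_peak_at_f0(self, profile):
        rec, tiv = gen_recording(profile, 300, seed=2)
        long_bursts = [(s, e) for s, e in tiv.intervals if e - s >= 8]
        assert long_bursts
        s, e = long_bursts[0]
        mid = rec.samples[int((s + 2) * 100) : int((e - 2) * 100), 0]
        mid = mid - mid.mean()
        freqs = np.fft.rfftfreq(len(mid), 1 / 100.0)
        spec = np.abs(np.fft.rfft(mid))
        band = (freqs > 3) & (freqs < 9)
        peak = freqs[band][np.argmax(spec[band])]
        assert peak == pytest.approx(profile.f0, abs=0.3)

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            SubjectProfile(subject_id="p", f0=12.0)
        with pytest.raises(ValueError):
            SubjectProfile(subject_id="p", tremor_prevalence=1.5)

    def test_short_duration_rejected(self, profile):
        with pytest.raises(ValueError):
            gen_recording(profile, 30, seed=0)


class TestWeakLabels:
    def test_full_tremor_interval_almost_always(self, profile):
        tiv = pp.TremorIntervalSet([(0.0, 4000.0)])
        entries = gen_weak_labels(tiv, 3600.0, profile=None)
        assert entries[0].label == "almost_always"

    def test_half_fraction_half_the_time(self):
        # exactly 150 s of tremor inside the 5-minute diary window
        tiv = pp.TremorIntervalSet([(3300.0 + 75.0, 3300.0 + 225.0)])
        entries = gen_weak_labels(tiv, 3600.0)
        assert entries[0].label == "half_the_time"

    def test_noise_free_labels_match_fraction_oracle(self):
        rng = np.random.default_rng(0)
        ivs = sorted(rng.uniform(0, 7000, size=(12, 1)).ravel())
        tiv = pp.TremorIntervalSet(
            [(s, s + rng.uniform(5, 120)) for s in ivs]
        )
        entries = gen_weak_labels(tiv, 7200.0, entry_period_s=600.0)
        assert len(entries) == 12
        for e in entries:
            frac = tiv.overlap(*e.interval) / 300.0
            assert e.label == percent_to_weak_label(100 * frac)

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            gen_weak_labels(pp.TremorIntervalSet([]), 100.0, entry_period_s=300.0)


class TestCohort:
    def test_recording_count_and_prevalence_spread(self):
        cohort = gen_cohort(6, seed=4, config={"duration_s": 60.0})
        assert len(cohort.recordings) == 12
        prevs = [p.tremor_prevalence for p in cohort.profiles.values()]
        assert min(prevs) <= 0.05
        assert max(prevs) >= 0.60

    def test_empirical_fraction_tracks_prevalence(self):
        cohort = gen_cohort(2, seed=8, config={"duration_s": 3600.0})
        for key, tiv in cohort.intervals.items():
            prof = cohort.profiles[key]
            frac = tiv.total_duration() / 3600.0
            assert frac == pytest.approx(prof.tremor_prevalence, abs=0.12)

    def test_window_truth_obeys_majority_rule(self, small_cohort):
        rec = small_cohort.recordings[3]
        key = (rec.subject_id, rec.hand)
        ws = tk.process_recording(rec, small_cohort.intervals[key])
        tiv = small_cohort.intervals[key]
        for i, start in enumerate(ws.window_start_s):
            assert ws.label[i] == int(tiv.overlap(start, start + 3.0) > 1.5)

    def test_manifest_records_profiles(self):
        cohort = gen_cohort(2, seed=1, config={"duration_s": 60.0})
        assert cohort.manifest["n_subjects"] == 2
        assert len(cohort.manifest["profiles"]) == 4

    def test_save_cohort_round_trip(self, tmp_path):
        cohort = gen_cohort(2, seed=2, config={"duration_s": 60.0})
        tk.synth.save_cohort(cohort, tmp_path)
        rec = cohort.recordings[0]
        back = pp.load_recording(tmp_path / f"{rec.subject_id}_{rec.hand}.csv")
        np.testing.assert_array_equal(back.samples, rec.samples)
        assert (tmp_path / "manifest.json").exists()


class TestEndToEnd:
    def test_oracle_percent_tremor_matches_ground_truth(self, small_cohort):
        # an oracle classifier (true window labels) must reproduce the
        # generator's tremor fraction within 2 points over the session
        from tremorkit.evaluate import percent_tremor

        rec = small_cohort.recordings[2]
        key = (rec.subject_id, rec.hand)
        tiv = small_cohort.intervals[key]
        ws = tk.process_recording(rec, tiv)
        pct = percent_tremor(ws.label, period_s=10_000)[0]
        truth = 100.0 * tiv.total_duration() / rec.duration_s
        assert pct == pytest.approx(truth, abs=2.0)

    def test_percent_error_shrinks_with_period(self, small_cohort):
        # estimation error of percent-tremor is non-increasing (in
        # aggregate) as the averaging period grows
        from tremorkit.evaluate import percent_tremor

        errs = {}
        for period in (60, 150, 300):
            diffs = []
            for rec in small_cohort.recordings:
                key = (rec.subject_id, rec.hand)
                tiv = small_cohort.intervals[key]
                ws = tk.process_recording(rec, tiv)
                est = percent_tremor(ws.label, period_s=period)
                for k, e in enumerate(est):
                    t0, t1 = k * period, min((k + 1) * period, rec.duration_s)
                    truth = 100.0 * tiv.overlap(t0, t1) / (t1 - t0)
                    diffs.append(abs(e - truth))
            errs[period] = np.mean(diffs)
        assert errs[300] <= errs[60] + 0.5
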