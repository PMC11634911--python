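import numpy as np
import pytest

from phonolvp.preprocess_segment import (InsufficientDataError, MedSignal,
                                         NoStableSegmentError,
                                         compute_envelopes, compute_med,
                                         design_hr_bandpass, detect_r_peaks,
                                         estimate_hr, segment_beats,
                                         segment_record,
                                         select_stable_segment)
from phonolvp.signal_io import SignalRecord
from conftest import FS, match_beats, simulate_step


class TestRPeaks:
    def test_recovers_truth_r_times(self):
        record, truth = simulate_step(rate=100.0, duration=30.0)
        r = detect_r_peaks(record.channels["ECG"], FS)
        truth_r = truth.r_times[truth.r_times < record.duration - 0.05]
        assert len(r) == len(truth_r)
        errs = np.abs(r / FS - truth_r)
        assert np.all(errs <= 0.010)

    def test_scale_invariance(self, hfref_step_nf):
        record, _ = hfref_step_nf
        ecg = record.channels["ECG"]
        np.testing.assert_array_equal(detect_r_peaks(ecg, FS),
                                      detect_r_peaks(3.7 * ecg, FS))

    def test_flat_signal_yields_empty(self):
        assert len(detect_r_peaks(np.zeros(5000), FS)) == 0

    def test_short_signal_rejected(self):
        with pytest.raises(InsufficientDataError):
            detect_r_peaks(np.zeros(500), FS)

    def test_refractory_period(self, hfref_step_nf):
        record, _ = hfref_step_nf
        r = detect_r_peaks(record.channels["ECG"], FS)
        assert np.all(np.diff(r) >= 0.240 * FS)


class TestHeartRate:
    def test_uniform_rr(self):
        peaks = np.arange(0, 20) * 750
        assert estimate_hr(peaks, FS) == pytest.approx(80.0)

    def test_paced_160_with_jitter(self):
        rng = np.random.default_rng(1)
        rr = 0.375 * (1 + 0.02 * rng.standard_normal(100))
        peaks = np.round(np.cumsum(rr) * FS).astype(int)
        assert estimate_hr(peaks, FS) == pytest.approx(160.0, abs=2.0)

    def test_two_peaks_insufficient(self):
        with pytest.raises(InsufficientDataError):
            estimate_hr(np.array([0, 750]), FS)


class TestEnvelopes:
    def test_pure_tone_envelope(self):
        t = np.arange(0, 2.0, 1 / FS)
        x = np.sin(2 * np.pi * 40 * t)
        upper, lower = compute_envelopes(x, FS)
        interior = slice(200, -200)
        assert np.all(np.abs(upper[interior] - 1) < 0.02)
        assert np.all(np.abs(lower[interior] + 1) < 0.02)

    def test_constant_signal_gives_zero_med(self):
        x = np.full(2000, 3.5)
        upper, lower = compute_envelopes(x, FS)
        np.testing.assert_allclose(upper, lower)

    def test_amplitude_modulation_tracked(self):
        t = np.arange(0, 3.0, 1 / FS)
        mod = 1.0 + 0.5 * np.sin(2 * np.pi * 1.0 * t)
        x = mod * np.sin(2 * np.pi * 40 * t)
        # 30 ms window: wide enough for the 25 ms carrier period, short
        # enough that the 1 Hz modulation is locally constant
        upper, lower = compute_envelopes(x, FS, window=0.03)
        med = upper - lower
        interior = slice(300, -300)
        rel_err = np.abs(med[interior] - 2 * mod[interior]) / (2 * mod[interior])
        assert np.max(rel_err) < 0.05

    def test_upper_never_below_lower(self, hfref_step_nf):
        record, _ = hfref_step_nf
        upper, lower = compute_envelopes(record.channels["MIC"], FS)
        assert np.all(upper >= lower)

    def test_spline_method_available(self):
        t = np.arange(0, 1.0, 1 / FS)
        x = np.sin(2 * np.pi * 40 * t)
        upper, lower = compute_envelopes(x, FS, method="spline_peaks")
        assert len(upper) == len(x) and len(lower) == len(x)
        assert upper[300:-300].mean() > 0.8

    def test_tiny_window_rejected(self):
        with pytest.raises(ValueError):
            compute_envelopes(np.zeros(100), FS, window=0.001)


class TestMed:
    def test_med_raw_nonnegative_from_sliding_extrema(self, hfref_step_nf):
        record, _ = hfref_step_nf
        upper, lower = compute_envelopes(record.channels["MIC"], FS)
        med = compute_med(upper, lower, hr=78, sampling_rate=FS)
        assert np.all(med.med_raw >= 0)
        assert med.passband == pytest.approx((0.7 * 78 / 60, 1.3 * 78 / 60))

    def test_passband_gain_at_hr_and_third_harmonic(self):
        """Zero-phase response: ~unit gain at the HR fundamental, strong
        rejection at the third harmonic."""
        import scipy.signal
        sos = design_hr_bandpass(78.0, FS)
        f0 = 78 / 60
        w, h = scipy.signal.sosfreqz(sos, worN=[f0, 3 * f0], fs=FS)
        gains = np.abs(h) ** 2  # forward-backward application squares |H|
        assert gains[0] >= 0.9
        assert gains[1] <= 0.1

    def test_equal_envelopes_give_zero_filtered(self):
        x = np.random.default_rng(0).random(5000)
        med = compute_med(x, x, hr=80, sampling_rate=FS)
        assert np.max(np.abs(med.med_filtered)) < 1e-12

    def test_filtered_output_has_zero_mean(self, hfref_step_nf):
        record, _ = hfref_step_nf
        upper, lower = compute_envelopes(record.channels["MIC"], FS)
        med = compute_med(upper, lower, hr=78, sampling_rate=FS)
        scale = np.max(np.abs(med.med_raw))
        assert abs(med.med_filtered.mean()) < 1e-6 * scale

    def test_passband_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            compute_med(np.ones(100), np.zeros(100), hr=250 * 60, sampling_rate=100)


class TestSegmentation:
    def test_boundaries_near_truth_end_systole(self, hfref_step_nf_segmented):
        record, truth, seg, _ = hfref_step_nf_segmented
        errs = []
        for k, j in match_beats(seg.r_peaks[:-1] / FS, truth):
            if seg.valid[k]:
                errs.append(seg.boundaries[k] / FS - truth.end_systole_times[j])
        errs = np.abs(errs)
        assert np.mean(errs <= 0.030) >= 0.95

    def test_beat_count_is_npeaks_minus_one(self, hfref_step_nf_segmented):
        _, _, seg, _ = hfref_step_nf_segmented
        assert seg.n_beats == len(seg.r_peaks) - 1

    def test_valid_boundaries_inside_beat(self, hfref_step_nf_segmented):
        _, _, seg, _ = hfref_step_nf_segmented
        for i in seg.valid_indices():
            assert seg.r_peaks[i] < seg.boundaries[i] < seg.r_peaks[i + 1]

    def test_constant_med_flags_all_beats(self):
        n = 5000
        med = MedSignal(upper=np.ones(n), lower=np.zeros(n),
                        med_raw=np.ones(n), med_filtered=np.zeros(n),
                        method="sliding_extrema", passband=(0.9, 1.7))
        seg = segment_beats(med, np.array([500, 1250, 2000, 2750]), FS)
        assert not seg.valid.any()
        assert set(seg.reasons) == {"no_med_minimum"}

    def test_too_few_peaks_rejected(self):
        n = 1000
        med = MedSignal(np.ones(n), np.zeros(n), np.ones(n), np.zeros(n),
                        "sliding_extrema", (0.9, 1.7))
        with pytest.raises(InsufficientDataError):
            segment_beats(med, np.array([100]), FS)

    def test_short_rr_flagged(self, hfref_step_nf_segmented):
        record, _, _, med = hfref_step_nf_segmented
        peaks = np.array([1000, 1100, 2000, 2800])
        seg = segment_beats(med, peaks, FS)
        assert seg.reasons[0] == "rr_too_short"

    def test_mic_scale_invariance_of_boundaries(self, hfref_step_nf):
        record, _ = hfref_step_nf
        seg1, _ = segment_record(record)
        scaled = SignalRecord(record.sampling_rate,
                              {**record.channels,
                               "MIC": 5.0 * record.channels["MIC"]})
        seg2, _ = segment_record(scaled)
        np.testing.assert_array_equal(seg1.boundaries, seg2.boundaries)


class TestStableSegment:
    def _toy_record(self, proxies, fs=250.0, rr=0.75):
        """LVP rectangles encoding per-beat peak values."""
        n_beats = len(proxies)
        n = int((n_beats + 1) * rr * fs)
        lvp = np.zeros(n)
        peaks = (np.arange(n_beats + 1) * rr * fs).astype(int)
        for i, p in enumerate(proxies):
            lvp[peaks[i]:peaks[i + 1]] = p
        rec = SignalRecord(fs, {"ECG": np.zeros(n), "MIC": np.zeros(n),
                                "POX": np.zeros(n), "LVP": lvp})
        return rec, peaks

    def test_stationary_record_returns_full_extent(self):
        rec, peaks = self._toy_record(np.full(280, 80.0))
        start, end = select_stable_segment(rec, peaks, min_duration=180)
        assert (start, end) == (0, rec.n_samples)

    def test_drift_region_excluded(self):
        proxies = np.full(400, 80.0)
        proxies[150:230] = 80.0 * np.linspace(1.0, 1.25, 80)  # +25% drift
        rec, peaks = self._toy_record(proxies)
        start, end = select_stable_segment(rec, peaks, min_duration=60)
        # the returned window avoids the drifted tail of the ramp
        sel = proxies[(peaks[:-1] >= start) & (peaks[1:] <= end)]
        med = np.median(sel)
        assert np.all(sel <= 1.10 * med) and np.all(sel >= 0.90 * med)
        assert (end - start) / rec.sampling_rate >= 60

    def test_short_record_raises_with_best_duration(self):
        rec, peaks = self._toy_record(np.full(60, 80.0))
        with pytest.raises(NoStableSegmentError) as exc:
            select_stable_segment(rec, peaks, min_duration=180)
        assert exc.value.best_duration < 180
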