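import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from phonolvp.beat_features import (DegenerateSpectrumError, MelSpectrogram,
                                    SpectroConfig, assemble_feature_table,
                                    compute_invptt, hz_to_mel, mel_filterbank,
                                    mel_spectrogram, mfcc_delta_delta,
                                    predictor_columns, spectral_features_setA)
from phonolvp.preprocess_segment import (InsufficientDataError,
                                         segment_record)
from conftest import FS, match_beats
from _oracles import mfcc_dd_oracle, setA_oracle

#: no dynamic-range floor — oracles compare against the pure-log definition
PURE_CFG = SpectroConfig(floor_db=None)


def make_spec(energies, centers=None):
    energies = np.asarray(energies, float)
    nb = energies.shape[1]
    centers = np.asarray(centers if centers is not None
                         else np.linspace(30, 140, nb), float)
    return MelSpectrogram(frame_times=np.arange(len(energies)) * 0.01,
                          band_centers=centers, energies=energies,
                          frame_length=0.05, hop=0.01)


class TestInvPtt:
    def test_reciprocal_of_known_delay(self):
        """A pulse whose maximum upslope lags each R peak by exactly 200 ms
        yields invPTT = 5 s^-1."""
        n = int(5 * FS)
        t = np.arange(n) / FS
        pox = np.zeros(n)
        peaks = (np.arange(1, 5) * FS).astype(int)
        tr = 0.1
        for r in peaks / FS:
            t0 = r + 0.2 - tr / 2
            u = t - t0
            m = (u >= 0) & (u <= tr)
            pox[m] += (1 - np.cos(np.pi * u[m] / tr)) / 2
        res = compute_invptt(peaks, pox, FS)
        assert res.valid[:-1].all()
        np.testing.assert_allclose(res.invptt[:-1], 5.0, rtol=0.02)

    def test_recovers_simulator_ptt(self, hfref_step_nf_segmented):
        record, truth, seg, _ = hfref_step_nf_segmented
        res = compute_invptt(seg.r_peaks, record.channels["POX"], FS)
        for k, j in match_beats(seg.r_peaks[:-1] / FS, truth):
            if res.valid[k]:
                assert res.invptt[k] == pytest.approx(1 / truth.ptt[j], rel=0.03)

    def test_constant_pox_flags_all(self):
        res = compute_invptt(np.array([1000, 2000, 3000]), np.ones(4000), FS)
        assert not res.valid.any()
        assert set(res.reasons) == {"no_pox_upstroke"}

    def test_empty_peaks_rejected(self):
        with pytest.raises(InsufficientDataError):
            compute_invptt(np.array([100]), np.zeros(1000), FS)


class TestMelSpectrogram:
    def test_frame_count_formula(self):
        cfg = SpectroConfig(frame=0.025, hop=0.010)
        spec = mel_spectrogram(np.random.default_rng(0).random(300), FS, cfg)
        assert spec.n_frames == (300 - 25) // 10 + 1 == 28

    def test_short_segment_single_zero_padded_frame(self):
        spec = mel_spectrogram(np.ones(10), FS)
        assert spec.n_frames == 1

    def test_zero_segment_zero_energies(self):
        spec = mel_spectrogram(np.zeros(500), FS)
        assert np.all(spec.energies == 0)

    def test_tone_at_band_center_dominates_that_band(self):
        cfg = SpectroConfig()
        fb, centers = mel_filterbank(FS, 256, cfg.n_bands, cfg.fmin, cfg.fmax)
        t = np.arange(0, 1.0, 1 / FS)
        for k in (5, 16, 28):
            spec = mel_spectrogram(np.sin(2 * np.pi * centers[k] * t), FS, cfg)
            assert np.all(spec.energies.argmax(axis=1) == k)

    def test_band_centers_increasing_energies_nonnegative(self, hfref_step_nf):
        record, _ = hfref_step_nf
        spec = mel_spectrogram(record.channels["MIC"][:2000], FS)
        assert np.all(np.diff(spec.band_centers) > 0)
        assert np.all(spec.energies >= 0)

    def test_band_range_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            mel_spectrogram(np.zeros(500), FS, SpectroConfig(fmax=600))

    def test_htk_mel_scale(self):
        assert hz_to_mel(700.0) == pytest.approx(2595 * np.log10(2))


class TestSetA:
    def test_two_point_symmetric_spectrum(self):
        e = np.zeros((3, 8))
        e[:, 2] = 1.0
        e[:, 5] = 1.0
        flux, kurt, skew, slope = spectral_features_setA(make_spec(e))
        assert skew == pytest.approx(0.0, abs=1e-12)
        assert kurt == pytest.approx(1.0, abs=1e-12)
        assert flux == pytest.approx(0.0, abs=1e-12)  # identical frames

    def test_flat_spectrum(self):
        e = np.full((4, 8), 3.0)
        flux, kurt, skew, slope = spectral_features_setA(make_spec(e))
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_frames_degenerate(self):
        with pytest.raises(DegenerateSpectrumError):
            spectral_features_setA(make_spec(np.zeros((4, 8))))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hnp.arrays(float, (5, 8),
                      elements=st.floats(0.0, 10.0)))
    def test_matches_brute_force_oracle(self, energies):
        energies = energies + 0.01  # keep frames non-degenerate
        centers = np.linspace(30, 140, 8)
        spec = make_spec(energies, centers)
        got = spectral_features_setA(spec)
        want = setA_oracle(energies, centers)
        np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-10)

    def test_scale_invariance_except_slope(self):
        rng = np.random.default_rng(3)
        e = rng.random((6, 8)) + 0.05
        spec = make_spec(e)
        f1, k1, s1, sl1 = spectral_features_setA(spec)
        f2, k2, s2, sl2 = spectral_features_setA(make_spec(9.0 * e))
        assert f2 == pytest.approx(f1, rel=1e-12)
        assert k2 == pytest.approx(k1, rel=1e-12)
        assert s2 == pytest.approx(s1, rel=1e-12)
        # band energies are power quantities: slope scales with the gain
        assert sl2 == pytest.approx(9.0 * sl1, rel=1e-12)


class TestSetB:
    def test_length_is_13(self):
        e = np.random.default_rng(0).random((6, 32))
        assert mfcc_delta_delta(make_spec(e, np.linspace(25, 145, 32))).shape == (13,)

    def test_constant_frames_give_zero(self):
        e = np.tile(np.random.default_rng(1).random(32), (7, 1))
        dd = mfcc_delta_delta(make_spec(e, np.linspace(25, 145, 32)))
        np.testing.assert_allclose(dd, 0.0, atol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hnp.arrays(float, (7, 32), elements=st.floats(0.0, 5.0)))
    def test_matches_dct_delta_oracle(self, energies):
        spec = make_spec(energies, np.linspace(25, 145, 32))
        got = mfcc_delta_delta(spec, PURE_CFG)
        want = mfcc_dd_oracle(energies, PURE_CFG.log_floor)
        np.testing.assert_allclose(got, want, rtol=1e-8, atol=1e-8)

    def test_scale_invariance(self):
        """A gain change adds a constant to the log energies (the relative
        floor scales with the signal), which the delta operator removes."""
        rng = np.random.default_rng(5)
        e = rng.random((9, 32)) * rng.choice([0.0, 1.0], (9, 32))
        spec = make_spec(e, np.linspace(25, 145, 32))
        d1 = mfcc_delta_delta(spec)
        d2 = mfcc_delta_delta(make_spec(137.0 * e, np.linspace(25, 145, 32)))
        np.testing.assert_allclose(d2, d1, atol=1e-8)

    def test_mfcc_first_switch(self):
        e = np.random.default_rng(2).random((6, 32))
        spec = make_spec(e, np.linspace(25, 145, 32))
        d0 = mfcc_delta_delta(spec, SpectroConfig(mfcc_first=0))
        d1 = mfcc_delta_delta(spec, SpectroConfig(mfcc_first=1))
        np.testing.assert_allclose(d0[1:], d1[:-1], atol=1e-12)


class TestAssembly:
    def test_predictor_vector_has_18_entries(self):
        for phase in ("sys", "dia"):
            cols = predictor_columns(phase)
            assert len(cols) == 18
            assert cols[0] == "invptt"
            assert sum("mfccdd" in c for c in cols) == 13

    def test_noise_free_simulation_all_beats_valid(self, hfref_step_nf_segmented):
        record, _, seg, _ = hfref_step_nf_segmented
        table = assemble_feature_table(seg, record.channels["MIC"],
                                       record.channels["POX"], FS)
        assert len(table.table) == seg.n_beats
        assert table.n_valid == int(seg.valid.sum())
        valid = table.table[table.table["valid"]]
        assert not valid[predictor_columns("sys")].isna().any().any()
        assert not valid[predictor_columns("dia")].isna().any().any()

    def test_determinism(self, hfref_step_nf_segmented):
        record, _, seg, _ = hfref_step_nf_segmented
        t1 = assemble_feature_table(seg, record.channels["MIC"],
                                    record.channels["POX"], FS).table
        t2 = assemble_feature_table(seg, record.channels["MIC"],
                                    record.channels["POX"], FS).table
        assert t1.equals(t2)
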