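"""Feature extraction: windowing, detectors, filters, band powers."""

import numpy as np
import pytest

from nocipipe import features as F
from nocipipe import synth


def _sine_signal(kind, rate, freq, duration, amp=1.0):
    t = np.arange(0, duration, 1.0 / rate)
    return F.RawSignal(kind=kind, rate=rate, samples=amp * np.sin(2 * np.pi * freq * t))


class TestSegmentWindows:
    def test_single_window(self):
        assert F.segment_windows(64.0) == [(0.0, 64.0)]

    def test_128s_gives_13_windows(self):
        assert len(F.segment_windows(128.0)) == 13

    def test_consecutive_windows_overlap_59s(self):
        ws = F.segment_windows(200.0)
        for (s0, e0), (s1, e1) in zip(ws, ws[1:]):
            assert e0 - s1 == pytest.approx(59.0)

    def test_too_short_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert F.segment_windows(40.0) == []


class TestRPeaks:
    def test_recall_against_generator_truth(self, short_session):
        b = short_session
        det = F.detect_r_peaks(b.ecg)
        gt = b.ground_truth["r_times_s"]
        matched = sum(np.min(np.abs(det - t)) < 0.02 for t in gt)
        assert matched / gt.size >= 0.99

    def test_all_zeros_yields_empty(self):
        sig = F.RawSignal(kind="ECG", rate=512.0, samples=np.zeros(512 * 10))
        with pytest.warns(UserWarning):
            assert F.detect_r_peaks(sig).size == 0

    def test_translation_equivariance(self, short_session):
        ecg = short_session.ecg
        shifted = F.RawSignal(kind="ECG", rate=ecg.rate,
                              samples=ecg.samples, start_s=100.0)
        a = F.detect_r_peaks(ecg)
        b = F.detect_r_peaks(shifted)
        assert np.allclose(b, a + 100.0)

    def test_wrong_kind_rejected(self, short_session):
        with pytest.raises(ValueError):
            F.detect_r_peaks(short_session.ppg)


class TestRRSeries:
    def test_unit_intervals(self):
        rr = F.rr_from_peaks(np.array([0.0, 1.0, 2.0]))
        assert np.allclose(rr.rr_ms, [1000.0, 1000.0])

    def test_mixed_intervals(self):
        rr = F.rr_from_peaks(np.array([0.0, 0.8, 1.7]))
        assert np.allclose(rr.rr_ms, [800.0, 900.0])

    def test_n_peaks_give_n_minus_1_intervals(self, rng):
        t = np.cumsum(rng.uniform(0.7, 1.1, 25))
        assert F.rr_from_peaks(t).rr_ms.size == 24

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            F.rr_from_peaks(np.array([0.0, 1.0, 0.5]))


def _modulated_rr(f0, duration=350.0, amp_ms=40.0):
    times = [0.0]
    while times[-1] < duration:
        t = times[-1]
        times.append(t + 0.85 + amp_ms / 1000.0 * np.sin(2 * np.pi * f0 * t))
    return F.rr_from_peaks(np.array(times))


class TestRRHF:
    def test_constant_rr_gives_zero(self):
        rr = F.rr_from_peaks(np.arange(0, 120, 0.85))
        hf = F.extract_rrhf(rr)
        assert np.max(np.abs(hf.values)) < 1e-6 * 850.0

    def test_in_band_modulation_preserved(self):
        rr = _modulated_rr(0.3)
        hf = F.extract_rrhf(rr)
        v = hf.values - hf.values.mean()
        win = np.hanning(v.size)
        amp = 2 * np.abs(np.fft.rfft(v * win)) / win.sum()
        freqs = np.fft.rfftfreq(v.size, 1.0 / hf.rate)
        out_amp = amp[np.argmin(np.abs(freqs - 0.3))]
        assert abs(out_amp - 40.0) / 40.0 < 0.20

    def test_out_of_band_modulation_rejected(self):
        rr_lo = _modulated_rr(0.05)
        hf = F.extract_rrhf(rr_lo)
        out_power = np.mean((hf.values - hf.values.mean()) ** 2)
        in_power = 40.0 ** 2 / 2.0  # sinusoidal modulation power
        assert out_power / in_power < 0.05

    def test_too_short_rejected(self):
        rr = F.rr_from_peaks(np.arange(0, 30, 0.85))
        with pytest.raises(ValueError):
            F.extract_rrhf(rr)


class TestRRHFPower:
    def test_zero_series_hits_floor(self):
        hf = F.RRHFSeries(time_s=np.arange(0, 64, 0.25),
                          values=np.zeros(256))
        p = F.rrhf_power(hf, [(0.0, 64.0)])
        assert p[0] == F.DB_FLOOR

    def test_sinusoid_power_matches_parseval_oracle(self):
        t = np.arange(0, 64, 0.25)
        x = np.sin(2 * np.pi * 0.3 * t)
        hf = F.RRHFSeries(time_s=t, values=x)
        p_db = F.rrhf_power(hf, [(0.0, 64.0)])[0]
        # oracle: direct tapered sum of squares on the same subsegments
        w = np.kaiser(64, 5.0)
        segs = x.reshape(4, 64)
        p_ref = np.mean([np.sum((s * w) ** 2) / np.sum(w ** 2) for s in segs])
        assert abs(10 ** (p_db / 10.0) - p_ref) / p_ref < 0.05

    def test_doubling_amplitude_adds_6dB(self):
        t = np.arange(0, 64, 0.25)
        x = np.sin(2 * np.pi * 0.3 * t)
        p1 = F.rrhf_power(F.RRHFSeries(time_s=t, values=x), [(0.0, 64.0)])[0]
        p2 = F.rrhf_power(F.RRHFSeries(time_s=t, values=2 * x), [(0.0, 64.0)])[0]
        assert p2 - p1 == pytest.approx(6.02, abs=0.05)

    def test_uncovered_window_yields_nan(self):
        t = np.arange(0, 64, 0.25)
        hf = F.RRHFSeries(time_s=t, values=np.ones(t.size))
        p = F.rrhf_power(hf, [(0.0, 64.0), (5.0, 69.0)])
        assert np.isfinite(p[0]) and np.isnan(p[1])


class TestPPGFilter:
    def test_dc_blocked(self):
        sig = F.RawSignal(kind="PPG", rate=128.0, samples=np.ones(128 * 30))
        out = F.filter_ppg(sig)
        assert np.max(np.abs(out.samples[128 * 5: -128 * 5])) < 1e-3

    def test_passband_gain_near_unity(self):
        sig = _sine_signal("PPG", 128.0, 1.5, 60.0)
        out = F.filter_ppg(sig)
        mid = out.samples[128 * 10: 128 * 50]
        gain_db = 20 * np.log10(np.max(np.abs(mid)))
        assert abs(gain_db) < 1.0

    def test_stopband_attenuation(self):
        sig = _sine_signal("PPG", 128.0, 30.0, 60.0)
        out = F.filter_ppg(sig)
        mid = out.samples[128 * 10: 128 * 50]
        assert 20 * np.log10(np.max(np.abs(mid))) < -20.0

    def test_low_rate_rejected(self):
        sig = F.RawSignal(kind="PPG", rate=10.0, samples=np.zeros(300))
        with pytest.raises(ValueError):
            F.filter_ppg(sig)


class TestPPGPeaks:
    def test_recall_and_count_on_clean_train(self):
        spec = synth.SessionSpec(duration_s=140.0, seed=0, baseline_hr=60.0,
                                 baseline_noci=0.0, hf_amp_ms=0.0,
                                 ppg_noise=0.0)
        tr = synth.gen_noci_trace(spec)
        sig, bt, _ = synth.gen_ppg(spec, tr)
        filt = F.filter_ppg(sig)
        pk_t, _ = F.detect_ppg_peaks(filt)
        sel = (bt >= 40.0) & (bt <= 100.0)
        n_true = int(sel.sum())
        in_win = pk_t[(pk_t >= 40.0) & (pk_t <= 100.0)]
        assert n_true - 1 <= in_win.size <= n_true + 1
        matched = sum(np.min(np.abs(pk_t - t)) < 0.05 for t in bt[sel])
        assert matched / n_true >= 0.99

    def test_amplitude_scaling_preserves_times(self, short_session):
        filt = F.filter_ppg(short_session.ppg)
        t1, a1 = F.detect_ppg_peaks(filt)
        doubled = F.RawSignal(kind="PPG", rate=filt.rate,
                              samples=2 * filt.samples)
        t2, a2 = F.detect_ppg_peaks(doubled)
        assert np.array_equal(t1, t2)
        assert np.allclose(a2, 2 * a1)

    def test_all_zeros_empty(self):
        sig = F.RawSignal(kind="PPG", rate=128.0, samples=np.zeros(128 * 20))
        t, a = F.detect_ppg_peaks(sig)
        assert t.size == 0 and a.size == 0


class TestPPGA:
    def test_constant_amplitude_train(self):
        t = np.arange(0.5, 120.0, 1.0)
        out = F.compute_ppga(t, np.ones(t.size), [(0.0, 64.0), (5.0, 69.0)])
        assert np.allclose(out, 1.0, atol=1e-6)

    def test_step_transitions_over_16s(self):
        t = np.arange(0.5, 200.0, 1.0)
        amp = np.where(t < 100.0, 1.0, 2.0)
        windows = [(s, s + 64.0) for s in np.arange(0.0, 130.0, 5.0)]
        out = F.compute_ppga(t, amp, windows)
        ends = np.array([e for _, e in windows])
        assert out[ends <= 92.0].max() < 1.01  # settled before the step
        assert out[ends >= 112.0].min() > 1.99  # settled after ~16 s
        mid = out[(ends > 92.0) & (ends < 112.0)]
        assert np.all(np.diff(mid) >= -1e-9)  # monotone transition

    def test_linearity_in_amplitude(self):
        t = np.arange(0.5, 120.0, 1.0)
        a = np.linspace(1.0, 2.0, t.size)
        w = [(0.0, 64.0), (10.0, 74.0)]
        out1 = F.compute_ppga(t, a, w)
        out3 = F.compute_ppga(t, 3 * a, w)
        assert np.allclose(out3, 3 * out1)

    def test_gap_warns(self):
        t = np.concatenate([np.arange(0.5, 30.0, 1.0),
                            np.arange(40.0, 70.0, 1.0)])
        with pytest.warns(UserWarning, match="gap"):
            F.compute_ppga(t, np.ones(t.size), [(0.0, 64.0)])


class TestPPGAUC:
    def test_zero_signal(self):
        sig = F.RawSignal(kind="PPG", rate=128.0, samples=np.zeros(128 * 70))
        assert F.compute_ppg_auc(sig, [(0.0, 64.0)])[0] == 0.0

    def test_rectified_sine_closed_form(self):
        sig = _sine_signal("PPG", 128.0, 1.0, 70.0)
        auc = F.compute_ppg_auc(sig, [(0.0, 64.0)])[0]
        expected = 64.0 * 2.0 / np.pi
        assert abs(auc - expected) / expected < 0.005

    def test_amplitude_linearity(self):
        sig = _sine_signal("PPG", 128.0, 1.0, 70.0)
        double = F.RawSignal(kind="PPG", rate=128.0, samples=2 * sig.samples)
        a1 = F.compute_ppg_auc(sig, [(0.0, 64.0)])[0]
        a2 = F.compute_ppg_auc(double, [(0.0, 64.0)])[0]
        assert a2 == pytest.approx(2 * a1)

    def test_partial_window_nan(self):
        sig = _sine_signal("PPG", 128.0, 1.0, 70.0)
        out = F.compute_ppg_auc(sig, [(20.0, 84.0)])
        assert np.isnan(out[0])


class TestEEGFilter:
    def test_dc_blocked(self):
        sig = F.RawSignal(kind="EEG", rate=128.0, samples=np.ones(128 * 30))
        out = F.filter_eeg(sig)
        assert np.max(np.abs(out.samples[128 * 5: -128 * 5])) < 1e-3

    def test_10hz_passes(self):
        out = F.filter_eeg(_sine_signal("EEG", 128.0, 10.0, 60.0))
        mid = out.samples[128 * 10: 128 * 50]
        assert abs(20 * np.log10(np.max(np.abs(mid)))) < 1.0

    def test_60hz_attenuated(self):
        out = F.filter_eeg(_sine_signal("EEG", 128.0, 60.0, 60.0))
        mid = out.samples[128 * 10: 128 * 50]
        assert 20 * np.log10(np.max(np.abs(mid))) < -20.0


class TestEEGBandPowers:
    def test_pure_tone_localized_to_alpha(self):
        sig = _sine_signal("EEG", 128.0, 10.0, 70.0)
        p = F.eeg_band_powers(sig, [(0.0, 64.0)])
        linear = {b: 10 ** (p[b][0] / 10.0) for b in p}
        total = sum(linear.values())
        assert linear["alpha"] / total >= 0.95

    def test_zero_signal_all_floor(self):
        sig = F.RawSignal(kind="EEG", rate=128.0, samples=np.zeros(128 * 70))
        p = F.eeg_band_powers(sig, [(0.0, 64.0)])
        for band in p:
            assert p[band][0] == F.DB_FLOOR

    def test_white_noise_power_proportional_to_bandwidth(self, rng):
        # 100 windows of white noise: linear band powers ~ bandwidth
        n_win = 100
        dur = 64.0 * n_win
        sig = F.RawSignal(kind="EEG", rate=128.0,
                          samples=rng.normal(0, 1, int(128 * dur)))
        windows = [(64.0 * k, 64.0 * (k + 1)) for k in range(n_win)]
        p = F.eeg_band_powers(sig, windows)
        mean_lin = {b: np.mean(10 ** (p[b] / 10.0)) for b in p}
        for band, (lo, hi) in F.EEG_BANDS.items():
            bw = hi - lo
            expected = bw / 64.0  # white noise PSD = 1/(fs/2) per Hz * bw
            assert abs(mean_lin[band] - expected) / expected < 0.10


class TestFeatureMatrix:
    def test_channel_count_and_rows(self, long_features):
        assert len(long_features.channels) == 8
        fm = long_features
        assert np.all(np.diff(fm.window_end_s) == 5.0)
        assert fm.window_end_s[0] == 64.0

    def test_128s_session_gives_13_rows(self):
        spec = synth.SessionSpec(duration_s=128.5, seed=4)
        b = synth.generate_session(spec)
        fm = F.build_feature_matrix(b.ecg, b.ppg, b.eeg)
        assert len(fm) == 13

    def test_csv_roundtrip_with_shuffled_columns(self, tmp_path,
                                                 long_features):
        import pandas as pd

        p = tmp_path / "features.csv"
        long_features.to_csv(p)
        df = pd.read_csv(p)
        shuffled = df[["window_end_s", "ppga", "delta", "gamma", "alpha",
                       "ppg_auc", "theta", "rrhf_ps", "beta"]]
        p2 = tmp_path / "shuffled.csv"
        shuffled.to_csv(p2, index=False)
        fm2 = F.FeatureMatrix.from_csv(p2)
        assert np.allclose(fm2.values, long_features.values)
        assert fm2.channels == long_features.channels

    def test_no_common_interval_rejected(self):
        a = F.RawSignal(kind="ECG", rate=512.0, samples=np.zeros(512 * 70))
        b = F.RawSignal(kind="PPG", rate=128.0, samples=np.zeros(128 * 70),
                        start_s=200.0)
        c = F.RawSignal(kind="EEG", rate=128.0, samples=np.zeros(128 * 70))
        with pytest.raises(ValueError, match="common interval"):
            F.build_feature_matrix(a, b, c)

    def test_feature_trace_coupling_signs(self, long_session, long_features):
        """On a clean 30 min session every coupled feature correlates with
        the latent trace in the physiological direction at |r| >= 0.3."""
        fm = long_features
        truth = long_session.truth_noci.at(fm.window_end_s)
        r = {ch: np.corrcoef(fm.data[ch], truth)[0, 1] for ch in fm.channels}
        assert r["delta"] >= 0.3
        assert r["alpha"] <= -0.3
        assert r["ppga"] <= -0.3
        assert r["ppg_auc"] >= 0.3

    def test_power_linear_scale_nonnegative(self, long_features):
        # dB values imply positive linear powers by construction
        for ch in ("delta", "theta", "alpha", "beta", "gamma", "rrhf_ps"):
            assert np.all(10 ** (long_features.data[ch] / 10.0) > 0)


class TestZeroPhase:
    def test_symmetric_pulse_stays_symmetric(self):
        # zero-phase filtering must not introduce group delay
        n = 128 * 30
        x = np.zeros(n)
        c = n // 2
        x[c - 64: c + 65] = np.hanning(129)
        sig = F.RawSignal(kind="PPG", rate=128.0, samples=x)
        out = F.filter_ppg(sig).samples
        peak = np.argmax(out)
        assert abs(peak - c) <= 1
        seg = out[c - 100: c + 101]
        assert np.allclose(seg, seg[::-1], atol=1e-6 * np.max(np.abs(seg)))
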