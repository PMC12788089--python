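"""Filtering, alignment and segmentation contracts."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import signal as sps

from dyadsense.config import AnalysisConfig
from dyadsense.preprocess import (
    derive_ecg,
    n_windows,
    resample_align,
    segment,
    zero_phase_bandpass,
    zero_phase_lowpass,
)
from dyadsense.streams import AlignmentError, Modality, SignalStream
from dyadsense.synth import GroundTruth, generate_ecg


def _stream(x, fs, start=0.0, modality=Modality.PUPIL, labels=None, name="s"):
    x = np.atleast_2d(np.asarray(x, dtype=float).T).T
    labels = labels or [f"ch{i}" for i in range(x.shape[1])]
    t = start + np.arange(x.shape[0]) / fs
    return SignalStream(name, modality, labels, fs, t, x)


def _sine(f, fs, T, phase=0.0):
    t = np.arange(int(T * fs)) / fs
    return np.sin(2 * np.pi * f * t + phase), t


class TestDeriveEcg:
    def test_identical_leads_give_zero(self):
        x = np.random.default_rng(0).normal(size=500)
        s = _stream(np.column_stack([x, x]), 500.0, modality=Modality.ECG)
        assert np.all(derive_ecg(s).samples == 0.0)

    def test_constant_offset_preserved(self):
        x = np.random.default_rng(0).normal(size=500)
        s = _stream(np.column_stack([x + 2.5, x]), 500.0, modality=Modality.ECG)
        np.testing.assert_allclose(derive_ecg(s).samples[:, 0], 2.5)

    def test_mismatched_grids_rejected(self):
        a = _stream(np.zeros(100), 500.0, start=0.0, modality=Modality.ECG)
        b = _stream(np.zeros(100), 500.0, start=0.1, modality=Modality.ECG)
        with pytest.raises(AlignmentError):
            derive_ecg(a, b)

    def test_recovers_injected_qrs_train(self):
        gt = GroundTruth(mean_hr=66.0, hr_sd=1.0, duration=20.0, seed=2)
        s = generate_ecg(gt, noise_sd=0.0, baseline_amp=0.3)
        d = derive_ecg(s)
        peaks = np.array(s.meta["r_peak_times"])
        idx = np.round((peaks - s.timestamps[0]) * s.fs_native).astype(int)
        assert np.all(d.samples[idx, 0] > 0.9)


class TestZeroPhaseFilters:
    def test_passband_unity_gain(self):
        x, _ = _sine(10.0, 500.0, 20.0)
        s = _stream(x, 500.0)
        y = zero_phase_bandpass(s, 2.0, 30.0).samples[:, 0]
        core = slice(1000, -1000)  # discard 2 s edges
        assert abs(np.max(np.abs(y[core])) - 1.0) < 0.01

    def test_dc_rejection(self):
        s = _stream(np.full(10000, 5.0), 500.0)
        y = zero_phase_bandpass(s, 2.0, 30.0).samples[1000:-1000, 0]
        assert np.max(np.abs(y)) < 0.05  # < 1% of the 5.0 offset

    def test_stopband_attenuation_matches_design_oracle(self):
        # oracle: squared magnitude response of the designed filter
        # (forward-backward application doubles the dB attenuation)
        fs = 100.0
        sos = sps.butter(4, [0.1, 0.5], btype="band", fs=fs, output="sos")
        w, h = sps.sosfreqz(sos, worN=[0.05], fs=fs)
        atten_db = -20 * np.log10(np.abs(h[0]) ** 2)
        assert atten_db > 20.0

        x, _ = _sine(0.05, fs, 400.0)
        s = _stream(x, fs)
        y = zero_phase_bandpass(s, 0.1, 0.5).samples[:, 0]
        core = slice(int(100 * fs), -int(100 * fs))
        measured = np.max(np.abs(y[core]))
        assert measured < 10 ** (-20 / 20)

    def test_zero_phase_no_lag(self):
        x, _ = _sine(5.0, 500.0, 10.0)
        s = _stream(x, 500.0)
        y = zero_phase_bandpass(s, 2.0, 30.0).samples[:, 0]
        xc = np.correlate(x[1000:-1000], y[1000:-1000], mode="full")
        lag = np.argmax(xc) - (len(x[1000:-1000]) - 1)
        assert lag == 0

    def test_passband_idempotence(self):
        x, _ = _sine(10.0, 500.0, 20.0)
        s = _stream(x, 500.0)
        once = zero_phase_bandpass(s, 2.0, 30.0)
        twice = zero_phase_bandpass(once, 2.0, 30.0)
        core = slice(1000, -1000)
        a1 = np.max(np.abs(once.samples[core, 0]))
        a2 = np.max(np.abs(twice.samples[core, 0]))
        assert abs(a2 - a1) / a1 < 0.02

    def test_band_outside_nyquist_rejected(self):
        s = _stream(np.zeros(1000), 100.0)
        with pytest.raises(ValueError):
            zero_phase_bandpass(s, 2.0, 60.0)
        with pytest.raises(ValueError):
            zero_phase_lowpass(s, 50.0)  # exactly Nyquist

    def test_nan_gaps_survive_filtering(self):
        x, _ = _sine(10.0, 200.0, 10.0)
        x[300:350] = np.nan
        s = _stream(x, 200.0)
        y = zero_phase_lowpass(s, 50.0).samples[:, 0]
        assert np.isnan(y[300:350]).all()
        assert not np.isnan(np.delete(y, slice(300, 350))).any()


class TestResampleAlign:
    def test_linear_ramp_exact(self, cfg):
        t = np.arange(5000) / 500.0
        s = _stream(2.0 * t + 1.0, 500.0)
        a = resample_align([s], cfg)
        np.testing.assert_allclose(a.data[:, 0], 2.0 * a.times + 1.0, atol=1e-12)

    def test_intersection_starts_at_later_stream(self, cfg):
        s1 = _stream(np.zeros(5000), 500.0, start=0.0)
        s2 = _stream(np.zeros(4000), 500.0, start=0.5, name="s2")
        a = resample_align([s1, s2], cfg)
        assert a.t0 == pytest.approx(0.5)

    def test_sinusoid_resampling_error_below_one_percent(self, cfg):
        x, t = _sine(3.0, 200.0, 10.0)
        s = _stream(x, 200.0)
        a = resample_align([s], cfg)
        ref = np.sin(2 * np.pi * 3.0 * a.times)
        rms = np.sqrt(np.mean((a.data[:, 0] - ref) ** 2))
        assert rms < 0.01

    def test_no_common_interval_rejected(self, cfg):
        s1 = _stream(np.zeros(100), 100.0, start=0.0)
        s2 = _stream(np.zeros(100), 100.0, start=50.0, name="s2")
        with pytest.raises(AlignmentError):
            resample_align([s1, s2], cfg)

    def test_impulse_time_preserved_within_one_grid_sample(self, cfg):
        # pipeline path: anti-alias low-pass widens the impulse so the
        # common grid cannot straddle it, then alignment must keep its time
        x = np.zeros(5000)
        t_star = 4.272
        x[int(round(t_star * 500))] = 1.0
        s = zero_phase_lowpass(_stream(x, 500.0), 50.0)
        a = resample_align([s], cfg)
        t_peak = a.times[np.argmax(a.data[:, 0])]
        assert abs(t_peak - t_star) <= 1.0 / cfg.fs_common

    def test_hand_carried_sample_and_hold(self, cfg):
        vals = np.array([0.0, 1.0, 1.0, 0.0, 1.0])
        s = _stream(vals, 1.0, modality=Modality.HAND)
        a = resample_align([s], cfg)
        # value at t=1.5 must be the 1.0 annotated at t=1, not interpolated
        i = np.argmin(np.abs(a.times - 1.5))
        assert a.data[i, 0] == 1.0

    def test_long_gap_flagged_invalid(self, cfg):
        x, _ = _sine(1.0, 200.0, 10.0)
        x[400:600] = np.nan  # 1 s gap > max_gap_s = 0.5
        s = _stream(x, 200.0)
        a = resample_align([s], cfg)
        gap = (a.times > 2.0) & (a.times < 3.0)
        assert a.invalid[gap, 0].any()
        assert not np.isnan(a.data).any()


class TestSegment:
    def _aligned(self, T, cfg):
        s = _stream(np.zeros(int(T * 100) + 1), 100.0)
        return resample_align([s], cfg)

    @pytest.mark.parametrize("T, expected", [(300.0, 55), (30.0, 1)])
    def test_window_counts(self, T, expected, cfg):
        assert len(segment(self._aligned(T, cfg), cfg)) == expected

    def test_too_short_warns_and_returns_empty(self, cfg):
        a = self._aligned(29.0, cfg)
        with pytest.warns(UserWarning):
            assert segment(a, cfg) == []

    def test_windows_labelled_by_end_time(self, cfg):
        wins = segment(self._aligned(300.0, cfg), cfg)
        assert wins[0].end_time == pytest.approx(30.0)
        assert wins[1].end_time == pytest.approx(35.0)
        assert wins[-1].end_time == pytest.approx(300.0)

    @given(
        T=st.floats(5.0, 400.0),
        L=st.floats(1.0, 60.0),
        S=st.floats(0.5, 30.0),
    )
    def test_count_matches_closed_form(self, T, L, S):
        if S > L:
            return
        cfg = AnalysisConfig(window_length=L, window_step=S)
        s = _stream(np.zeros(int(T * 100) + 1), 100.0)
        a = resample_align([s], cfg)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wins = segment(a, cfg)
        # compare against the closed form evaluated on the sample grid
        Ls, Ss = int(round(L * 100)), int(round(S * 100))
        expected = 0 if a.n_samples < Ls else (a.n_samples - Ls) // Ss + 1
        assert len(wins) == expected
        assert len(wins) == n_windows(a.n_samples, Ls, Ss)
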