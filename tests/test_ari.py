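"""Automatic ARI: window arithmetic, squared-derivative area offset,
invariances, per-beat series flags."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from stvrepol import (AlgoParams, SignalRecord, SynthConfig, beat_window,
                      detect_senses, measure_ari, measure_ari_series,
                      synthesize_record)


class TestBeatWindow:
    def test_default_arithmetic(self):
        assert beat_window(1000.0, 800.0, AlgoParams()) == (1200.0, 1750.0)

    def test_boundary_one_ms_window(self):
        p = AlgoParams(blanking_ms=200.0, window_guard_ms=50.0)
        assert beat_window(0.0, 251.0, p) == (200.0, 201.0)

    def test_custom_guard(self):
        p = AlgoParams(blanking_ms=200.0, window_guard_ms=100.0)
        assert beat_window(500.0, 600.0, p) == (700.0, 1000.0)


def _record_from_function(fn, duration_ms=700.0, fs=1000.0):
    t = np.arange(int(duration_ms * fs / 1000.0)) * (1000.0 / fs)
    return SignalRecord(fn(t)[None, :], fs=fs, channel_labels=["I2"])


def _dense_oracle(fn, window, frac, fs_dense=100_000.0):
    """Independent brute-force offset: dense sampling, gradient, squaring,
    trapezoidal cumulative integration, interpolated crossing."""
    t = np.arange(window[0], window[1], 1000.0 / fs_dense)
    s = np.gradient(fn(t), t) ** 2
    c = cumulative_trapezoid(s, t, initial=0.0)
    target = frac * c[-1]
    j = np.searchsorted(c, target)
    f = (target - c[j - 1]) / (c[j] - c[j - 1])
    return t[j - 1] + f * (t[j] - t[j - 1])


def _bump(center, width, amp=1.0):
    def fn(t):
        x = np.clip((t - center) / width, -1.0, 1.0)
        return amp * 0.5 * (1 + np.cos(np.pi * x)) * (np.abs(t - center) < width)
    return fn


class TestMeasureAri:
    def test_symmetric_bump_half_area_hits_centre(self):
        fn = _bump(400.0, 80.0)
        rec = _record_from_function(fn)
        p = AlgoParams(auc_fraction=0.5)
        ari, flag = measure_ari(rec, "I2", 0.0, (300.0, 500.0), p)
        assert flag == "ok"
        assert ari == pytest.approx(400.0, abs=1e-6)

    def test_sixty_percent_matches_dense_oracle(self):
        fn = _bump(400.0, 80.0)
        rec = _record_from_function(fn)
        ari, _ = measure_ari(rec, "I2", 0.0, (300.0, 500.0), AlgoParams())
        oracle = _dense_oracle(fn, (300.0, 500.0), 0.60)
        assert abs(ari - oracle) <= rec.dt_ms

    def test_oracle_equivalence_on_random_smooth_windows(self):
        # 100 random multi-bump windows vs the 100 kHz cumulative-area oracle
        rng = np.random.default_rng(42)
        p = AlgoParams()
        for _ in range(100):
            n_bumps = rng.integers(2, 6)
            centers = rng.uniform(320.0, 480.0, n_bumps)
            widths = rng.uniform(25.0, 80.0, n_bumps)
            amps = rng.uniform(-1.0, 1.0, n_bumps)

            def fn(t, c=centers, w=widths, a=amps):
                return sum(_bump(ci, wi, ai)(t) for ci, wi, ai in zip(c, w, a))

            rec = _record_from_function(fn)
            ari, flag = measure_ari(rec, "I2", 0.0, (250.0, 550.0), p)
            if flag == "noisy":
                continue  # degenerate bump cancellation
            oracle = _dense_oracle(fn, (250.0, 550.0), 0.60)
            assert abs(ari - oracle) <= rec.dt_ms

    @pytest.mark.parametrize("scale", [-3.0, -1.0, 0.5, 10.0])
    def test_polarity_and_scale_invariance(self, scale):
        fn = _bump(400.0, 70.0)
        rec = _record_from_function(fn)
        scaled = SignalRecord(rec.samples * scale, fs=rec.fs,
                              channel_labels=["I2"])
        a, _ = measure_ari(rec, "I2", 0.0, (300.0, 520.0), AlgoParams())
        b, _ = measure_ari(scaled, "I2", 0.0, (300.0, 520.0), AlgoParams())
        assert a == pytest.approx(b, abs=1e-12)

    def test_offset_monotone_in_auc_fraction(self):
        fn = _bump(400.0, 70.0)
        rec = _record_from_function(fn)
        offsets = [measure_ari(rec, "I2", 0.0, (300.0, 520.0),
                               AlgoParams(auc_fraction=f))[0]
                   for f in (0.2, 0.4, 0.5, 0.6, 0.8, 0.95)]
        assert np.all(np.diff(offsets) >= 0)

    def test_zero_energy_window_flagged_noisy(self):
        rec = SignalRecord(np.zeros((1, 1000)), fs=1000.0, channel_labels=["I2"])
        ari, flag = measure_ari(rec, "I2", 0.0, (200.0, 700.0), AlgoParams())
        assert np.isnan(ari) and flag == "noisy"

    def test_shift_equivariance_of_t_wave(self):
        # delaying the T-wave by delta shifts the ARI by delta (within a sample)
        delta = 12.0
        rec_a = _record_from_function(_bump(400.0, 70.0))
        rec_b = _record_from_function(_bump(400.0 + delta, 70.0))
        a, _ = measure_ari(rec_a, "I2", 0.0, (250.0, 550.0), AlgoParams())
        b, _ = measure_ari(rec_b, "I2", 0.0, (250.0, 550.0), AlgoParams())
        assert b - a == pytest.approx(delta, abs=rec_a.dt_ms)


class TestMeasureAriSeries:
    def test_clean_record_all_ok(self, clean_egm, sensed_egm):
        _, record, truth = clean_egm
        series = measure_ari_series(record, "I2", sensed_egm)
        assert len(series) == truth.n_beats
        assert sum(f == "ok" for f in series.flags) >= truth.n_beats - 1

    def test_ari_tracks_truth_landmarks(self, clean_egm, sensed_egm):
        # ARI differs from (t_end - sense) only by a near-constant offset
        _, record, truth = clean_egm
        series = measure_ari_series(record, "I2", sensed_egm)
        resid = series.ok_values() - (truth.t_end - series.sense_times)
        assert np.nanstd(resid) <= 0.5

    def test_low_t_amplitude_flagged(self):
        cfg = SynthConfig.egm(n_beats=10, t_amplitude=0.3, noise_sd=0.0,
                              repol_jitter_sd=0.0)
        record, _ = synthesize_record(cfg)
        senses = detect_senses(record, "I2")
        series = measure_ari_series(record, "I2", senses)
        assert all(f == "low_t_amplitude" for f in series.flags)

    def test_paced_beats_flagged_for_spike_interference(self):
        cfg = SynthConfig.egm(n_beats=12, noise_sd=0.0, repol_jitter_sd=0.0,
                              pacing={"enabled": True, "rate_offset_bpm": 20.0})
        record, truth = synthesize_record(cfg)
        senses = detect_senses(record, "I2")
        series = measure_ari_series(record, "I2", senses,
                                    beat_labels=truth.label)
        interfered = [f == "pacing_interference" for f in series.flags]
        # every beat whose window reaches the next spike is excluded
        assert sum(interfered) >= len(series) - 2

    def test_short_rr_gives_truncated_flag(self, clean_egm):
        from stvrepol import SenseSeries
        _, record, _ = clean_egm
        senses = SenseSeries(times=np.array([400.0, 640.0, 1400.0, 2150.0]))
        series = measure_ari_series(record, "I2", senses)
        assert series.flags[0] == "window_truncated"
        assert np.isnan(series.ari_ms[0])
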