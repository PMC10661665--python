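"""STV statistic, exclusion rule, QTc, ST-deviation, channel selection,
segment quality."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stvrepol import (AlgoParams, InsufficientDataError, NoChannelError,
                      ParameterError, SynthConfig, detect_senses,
                      ectopy_exclusion_mask, percent_change, qtc_bazett,
                      segment_quality, select_egm_channel, st_deviation, stv,
                      synthesize_record)

SQRT2 = np.sqrt(2.0)


class TestStv:
    def test_constant_series_is_zero(self):
        assert stv([400.0] * 31).value == 0.0

    def test_alternating_two_ms_gives_sqrt2(self):
        series = [500.0 + 2.0 * (k % 2) for k in range(31)]
        assert stv(series).value == pytest.approx(SQRT2, rel=1e-12)

    def test_unit_ramp_gives_inverse_sqrt2(self):
        series = [400.0 + k for k in range(31)]
        assert stv(series).value == pytest.approx(1.0 / SQRT2, rel=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        values=st.lists(st.floats(300.0, 500.0), min_size=2, max_size=40),
        shift=st.floats(-100.0, 100.0),
        scale=st.floats(-3.0, 3.0),
    )
    def test_shift_invariance_and_scale_equivariance(self, values, shift, scale):
        d = np.asarray(values)
        base = stv(d).value
        assert stv(d + shift).value == pytest.approx(base, abs=1e-9)
        assert stv(d * scale).value == pytest.approx(abs(scale) * base,
                                                     abs=1e-9)

    def test_gap_drops_spanning_pairs(self):
        # 0..9 ramp with beat 5 missing: pairs (4,5) and (5,6) are dropped
        d = np.arange(10, dtype=float) + 400.0
        d[5] = np.nan
        res = stv(d)
        assert res.n_pairs == 7
        assert res.n_excluded == 1
        assert res.value == pytest.approx(1.0 / SQRT2)

    def test_strict_mode_requires_31_consecutive(self):
        with pytest.raises(ParameterError):
            stv(np.arange(30, dtype=float), strict=True)
        d = np.arange(32, dtype=float)
        d[0] = np.nan
        assert stv(d, strict=True).n_pairs == 30

    def test_too_few_values_raise(self):
        with pytest.raises(InsufficientDataError):
            stv([400.0])

    def test_gaussian_expectation(self):
        # E[STV] = sigma * sqrt(2/pi) for iid Gaussian determinants
        rng = np.random.default_rng(100)
        sigma = 5.0
        vals = [stv(rng.normal(400.0, sigma, 31)).value for _ in range(2000)]
        assert np.mean(vals) == pytest.approx(sigma * np.sqrt(2 / np.pi),
                                              abs=0.15)


class TestEctopyExclusion:
    def test_single_ectopic_excludes_four_beats(self):
        labels = ["normal"] * 40
        labels[10] = "ectopic"
        keep = ectopy_exclusion_mask(labels)
        assert set(np.flatnonzero(~keep)) == {9, 10, 11, 12}
        assert keep.sum() == 36

    def test_boundary_clipping_at_start(self):
        labels = ["ectopic", "ectopic"] + ["normal"] * 8
        keep = ectopy_exclusion_mask(labels)
        assert set(np.flatnonzero(~keep)) == {0, 1, 2, 3}

    def test_no_ectopics_keeps_all(self):
        keep = ectopy_exclusion_mask(["normal"] * 12)
        assert keep.all()

    def test_paced_beats_excluded_for_t_wave_metrics(self):
        labels = ["normal", "paced", "normal"]
        assert list(ectopy_exclusion_mask(labels)) == [True, False, True]
        assert list(ectopy_exclusion_mask(labels, exclude_paced=False)) == \
            [True, True, True]

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        n=st.integers(2, 50),
        data=st.data(),
    )
    def test_matches_brute_force_set_rule(self, n, data):
        ect = data.draw(st.sets(st.integers(0, n - 1), max_size=5))
        labels = ["ectopic" if i in ect else "normal" for i in range(n)]
        keep = ectopy_exclusion_mask(labels)
        excluded = set()
        for e in ect:
            excluded |= {e - 1, e, e + 1, e + 2}
        excluded &= set(range(n))
        assert set(np.flatnonzero(~keep)) == excluded

    def test_idempotent_and_order_independent(self):
        labels = ["normal"] * 20
        for i in (3, 4, 11):
            labels[i] = "ectopic"
        keep = ectopy_exclusion_mask(labels)
        assert np.array_equal(keep, ectopy_exclusion_mask(labels))


class TestQtcAndPercentChange:
    @pytest.mark.parametrize("qt,rr,expected", [
        (400.0, 1000.0, 400.0),
        (448.0, 901.0, 471.97),
        (300.0, 250.0, 600.0),
    ])
    def test_bazett_examples(self, qt, rr, expected):
        assert qtc_bazett(qt, rr) == pytest.approx(expected, abs=0.01)

    def test_bazett_rejects_nonpositive(self):
        with pytest.raises(ParameterError):
            qtc_bazett(-1.0, 800.0)
        with pytest.raises(ParameterError):
            qtc_bazett(400.0, 0.0)

    @pytest.mark.parametrize("value,baseline,expected", [
        (1.0, 1.0, 0.0),
        (1.65, 0.58, 184.48),
        (0.5, 1.0, -50.0),
    ])
    def test_percent_change_examples(self, value, baseline, expected):
        assert percent_change(value, baseline) == pytest.approx(expected,
                                                                abs=0.01)

    def test_percent_change_rejects_zero_baseline(self):
        with pytest.raises(ParameterError):
            percent_change(1.0, 0.0)


class TestStDeviation:
    def test_zero_st_record_measures_zero(self, clean_ecg):
        _, record, _ = clean_ecg
        senses = detect_senses(record, "V2")
        assert st_deviation(record, "V2", senses) == pytest.approx(0.0,
                                                                   abs=0.01)

    def test_programmed_elevation_recovered(self):
        cfg = SynthConfig.ecg(n_beats=15, st_deviation=0.15, noise_sd=0.0,
                              repol_jitter_sd=0.0)
        record, _ = synthesize_record(cfg)
        senses = detect_senses(record, "V2")
        assert st_deviation(record, "V2", senses) == pytest.approx(0.15,
                                                                   abs=0.01)

    def test_dc_offset_cancels(self, clean_ecg):
        from stvrepol import SignalRecord
        _, record, _ = clean_ecg
        senses = detect_senses(record, "V2")
        offset = SignalRecord(record.samples + 1.0, fs=record.fs,
                              channel_labels=["V2"])
        a = st_deviation(record, "V2", senses)
        b = st_deviation(offset, "V2", senses)
        assert a == pytest.approx(b, abs=1e-9)


class TestChannelSelection:
    def _record(self, st_devs, t_amps, n_beats=12):
        overrides = {
            f"I{i+1}": {"st_deviation": sd, "t_amplitude": ta}
            for i, (sd, ta) in enumerate(zip(st_devs, t_amps))
        }
        cfg = SynthConfig.egm(n_beats=n_beats, noise_sd=0.0,
                              repol_jitter_sd=0.0,
                              channel_labels=[f"I{i+1}" for i in
                                              range(len(st_devs))],
                              channel_overrides=overrides)
        record, _ = synthesize_record(cfg)
        senses = detect_senses(record, record.channel_labels[-1])
        return record, senses

    def test_injury_current_pole_rejected(self):
        record, senses = self._record([0.8, 0.1, 0.05], [1.0, 1.0, 1.0])
        channel, report = select_egm_channel(record, senses)
        assert channel == "I2"
        assert report["I1"]["reason"] is not None

    def test_all_low_amplitude_raises(self):
        record, senses = self._record([0.0, 0.0, 0.0], [0.3, 0.3, 0.3])
        with pytest.raises(NoChannelError) as exc:
            select_egm_channel(record, senses)
        assert set(exc.value.reasons) == {"I1", "I2", "I3"}

    def test_single_clean_channel_selected(self):
        record, senses = self._record([0.05], [1.0])
        channel, _ = select_egm_channel(record, senses)
        assert channel == "I1"


class TestSegmentQuality:
    def test_clean_segment_measurable(self, clean_egm, sensed_egm):
        _, record, truth = clean_egm
        q = segment_quality(record, "I2", sensed_egm, truth.label)
        assert q.measurable
        assert q.morphology_stability >= 0.9
        assert not q.pacing_present

    def test_paced_segment_unmeasurable(self):
        cfg = SynthConfig.egm(n_beats=12, noise_sd=0.0, repol_jitter_sd=0.0,
                              pacing={"enabled": True, "rate_offset_bpm": 20.0})
        record, truth = synthesize_record(cfg)
        senses = detect_senses(record, "I2")
        q = segment_quality(record, "I2", senses, truth.label)
        assert q.pacing_present and not q.measurable

    def test_heavy_ectopy_unmeasurable(self):
        cfg = SynthConfig.egm(n_beats=31, noise_sd=0.0, repol_jitter_sd=0.0,
                              ectopic_indices=[5, 12, 19, 26])
        record, truth = synthesize_record(cfg)
        senses = detect_senses(record, "I2")
        q = segment_quality(record, "I2", senses, truth.label)
        assert q.ectopy_fraction == pytest.approx(4 / 31)
        assert not q.measurable
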