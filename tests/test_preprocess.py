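"""Alignment, segmentation, aggregation, normalization, SNR, filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as stf

from pao2osc import preprocess as pp
from pao2osc import synthetic as syn
from pao2osc.core import DT, SignalTrace

from conftest import make_periodic_trace


class TestAlignment:
    def test_noiseless_kink_recovered_exactly(self):
        # decline -1 mmHg/s, kink 1.0 s after restart, rise +5 mmHg/s
        restart = 620.0
        t = np.arange(0, 6400) * DT
        kink = restart + 1.0
        pao2 = np.where(
            t < kink, 300.0 - 1.0 * (t - 600.0), 300.0 - (kink - 600.0) + 5.0 * (t - kink)
        )
        paw = np.where(np.mod(t, 60.0) < 20.0, 18.0, 5.0)
        paw[(t >= 600.0) & (t < restart)] = 5.0
        trace = SignalTrace(
            t=t, pao2=pao2, paw=paw,
            breath_hold_window=(600.0, restart), ventilation_restart_s=restart,
        )
        res = pp.detect_alignment_offset(trace)
        assert res.alignable
        assert res.method == "two_line_intersection"
        assert res.offset == pytest.approx(1.0, abs=1e-9)

    def test_flat_recovery_is_unalignable(self):
        spec = syn.ConditionSpec(
            "c", "A1", 8.0, 10.0, False, morphology=syn.ARCHETYPES[0],
            force_exclusion="unalignable",
        )
        trace, _ = syn.simulate_condition(spec, 8)
        res = pp.detect_alignment_offset(trace)
        assert not res.alignable
        assert res.offset is None

    def test_offset_recovery_band_at_30db(self):
        hits = 0
        for s in range(20):
            off = 0.8 + (s % 5) * 0.2
            spec = syn.ConditionSpec(
                "c", "A1", 8.0, 10.0, False, morphology=syn.ARCHETYPES[s % 5],
                snr_db=30.0, true_offset=off,
            )
            trace, _ = syn.simulate_condition(spec, 300 + s)
            res = pp.detect_alignment_offset(trace)
            hits += res.alignable and abs(res.offset - off) <= 0.2
        assert hits >= 18

    def test_missing_hold_window_is_an_error(self, clean_trace):
        broken = SignalTrace(
            t=clean_trace.t, pao2=clean_trace.pao2, paw=clean_trace.paw,
            breath_hold_window=None, ventilation_restart_s=620.0,
        )
        with pytest.raises(ValueError):
            pp.detect_alignment_offset(broken)


class TestSegmentation:
    def test_canonical_shape_10_by_600(self):
        trace = make_periodic_trace()
        mat = pp.segment_breaths(trace, offset=0.0)
        assert mat.values.shape == (10, 600)

    def test_periodic_input_gives_identical_rows(self):
        # offset 0: this hand-built trace has no ventilation-to-PaO2 lag
        trace = make_periodic_trace()
        mat = pp.segment_breaths(trace, offset=0.0)
        assert np.abs(mat.values - mat.values[0]).max() < 1e-9

    def test_phase_equivariance_under_whole_breath_shift(self):
        a = make_periodic_trace(n_breaths=12)
        b = make_periodic_trace(n_breaths=13)
        ma = pp.segment_breaths(a, offset=0.7)
        mb = pp.segment_breaths(b, offset=0.7)
        np.testing.assert_allclose(ma.values, mb.values, atol=1e-9)

    def test_too_short_trace_is_an_error(self):
        trace = make_periodic_trace(n_breaths=5)
        with pytest.raises(ValueError, match="too short"):
            pp.segment_breaths(trace, offset=0.0, n_breaths=10)


class TestDetrend:
    def test_pure_line_maps_to_zeros(self):
        t = np.arange(6000) * DT
        out = pp.detrend_linear(5.0 + 0.3 * t)
        np.testing.assert_allclose(out, 0.0, atol=1e-8)

    def test_constant_input_maps_to_zeros(self):
        np.testing.assert_array_equal(pp.detrend_linear(np.full(100, 7.0)), 0.0)

    def test_injected_slope_recovered(self):
        rng = np.random.default_rng(0)
        t = np.arange(6000) * DT
        clean = np.sin(2 * np.pi * t / 60.0) + rng.normal(0, 0.05, len(t))
        slope = 0.5
        signal = clean + slope * t
        out = pp.detrend_linear(signal)
        removed_slope = np.polyfit(t, signal - out, 1)[0]
        assert abs(removed_slope - slope) < 0.01
        assert abs(np.polyfit(t, out, 1)[0]) < 1e-10  # zero OLS slope out
        assert abs(out.mean()) < 1e-10


class TestAggregationNormalization:
    def test_median_of_identical_breaths_is_that_breath(self):
        row = np.sin(np.linspace(0, 2 * np.pi, 600))
        mat = pp.BreathMatrix(np.tile(row, (10, 1)))
        np.testing.assert_allclose(pp.aggregate_median_breath(mat), row, atol=1e-12)

    def test_median_rejects_a_fully_corrupted_breath(self):
        row = np.sin(np.linspace(0, 2 * np.pi, 600))
        rows = np.tile(row, (10, 1))
        rows[3] += 50.0
        mat = pp.BreathMatrix(rows)
        np.testing.assert_allclose(pp.aggregate_median_breath(mat), row, atol=1e-9)

    def test_median_attenuates_cardiac_ripple_tenfold(self):
        t = np.arange(600) * DT
        breath = np.sin(2 * np.pi * t / 60.0)
        f_c = 116.5 / 60.0  # beats/s, non-harmonic of the breath
        amp = 0.5
        rows = np.vstack(
            [breath + amp * np.sin(2 * np.pi * f_c * (t + 60.0 * k)) for k in range(10)]
        )
        med = pp.aggregate_median_breath(pp.BreathMatrix(rows))
        assert np.abs(med - breath).max() <= amp / 10.0

    def test_fewer_than_three_breaths_rejected(self):
        with pytest.raises(ValueError):
            pp.aggregate_median_breath(pp.BreathMatrix(np.zeros((2, 600))))

    @given(scale=stf.floats(0.1, 100.0), shift=stf.floats(-500.0, 500.0))
    @settings(max_examples=30, deadline=None)
    def test_normalization_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(1)
        breath = rng.normal(0, 1, 600)
        a = pp.normalize_breath(breath)
        b = pp.normalize_breath(scale * breath + shift)
        np.testing.assert_allclose(a.values, b.values, atol=1e-8)
        assert abs(a.values.mean()) < 1e-10
        assert abs(a.values.std() - 1.0) < 1e-10

    def test_normalization_idempotent(self):
        rng = np.random.default_rng(2)
        breath = rng.normal(5, 3, 600)
        once = pp.normalize_breath(breath)
        twice = pp.normalize_breath(once.values * 1.0 + 0.0)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_constant_breath_is_an_error(self):
        with pytest.raises(ValueError):
            pp.normalize_breath(np.full(600, 3.0))


class TestSNR:
    def test_equal_signal_and_noise_power_is_zero_db(self):
        rng = np.random.default_rng(3)
        t = np.arange(600) * DT
        breath = np.sqrt(2.0) * np.sin(2 * np.pi * t / 60.0)  # variance 1
        rows = np.vstack([breath + rng.normal(0, 1.0, 600) for _ in range(200)])
        mat = pp.BreathMatrix(rows, detrended=True)
        assert abs(pp.estimate_snr_db(mat)) < 1.0

    def test_noiseless_matrix_hits_the_cap(self):
        row = np.sin(np.linspace(0, 2 * np.pi, 600))
        mat = pp.BreathMatrix(np.tile(row, (10, 1)), detrended=True)
        assert pp.estimate_snr_db(mat) == pp.SNR_CAP_DB


class TestExclusionFilters:
    def _result(self, cid, trough, snr, alignable):
        return pp.ConditionResult(
            condition_id=cid,
            alignment=pp.AlignmentResult(
                offset=1.0 if alignable else None,
                method="change_point" if alignable else "none",
                alignable=alignable,
                decline_resid_sd=0.1,
            ),
            trough=trough,
            snr_db=snr,
        )

    def test_reason_order_and_partition(self):
        results = [
            self._result("a", 90.0, 10.0, False),  # fails all: trough recorded
            self._result("b", 150.0, 10.0, False),  # snr before alignment
            self._result("c", 150.0, 30.0, False),
            self._result("d", 150.0, 30.0, True),
        ]
        rep = pp.apply_exclusion_filters(results)
        assert rep.set_index("condition_id")["reason"].to_dict() == {
            "a": "trough_below_100mmHg",
            "b": "snr_below_20dB",
            "c": "unalignable",
            "d": "none",
        }
        assert int(rep["included"].sum()) + int((~rep["included"]).sum()) == 4

    def test_trough_boundary_is_strict(self):
        rep = pp.apply_exclusion_filters([self._result("x", 100.0, 30.0, True)])
        assert bool(rep.loc[0, "included"])

    def test_all_clean_cohort_has_zero_exclusions(self):
        results = [self._result(f"c{i}", 200.0, 30.0, True) for i in range(10)]
        rep = pp.apply_exclusion_filters(results)
        assert rep["included"].all()
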