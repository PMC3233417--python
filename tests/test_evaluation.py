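"""Fit statistics (AUC, AUC_r, MSSD, PE summaries) and sensitivity ratios."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pbpktk import evaluation
from pbpktk.errors import DataError, UnitError
from pbpktk.evaluation import (KineticDataset, auc_ratio, auc_trapezoid, mssd,
                               performance_errors, sensitivity_ratio,
                               sensitivity_screen)


class TestAUC:
    def test_constant_series(self):
        assert auc_trapezoid([0, 5], [2, 2]) == pytest.approx(10.0)

    def test_triangle(self):
        assert auc_trapezoid([0, 1, 2], [0, 1, 0]) == pytest.approx(1.0)

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(DataError):
            auc_trapezoid([1.0], [2.0])

    def test_matches_loop_oracle_on_random_series(self):
        rng = np.random.default_rng(7)
        t = np.sort(rng.uniform(0, 24, 50))
        t += np.arange(50) * 1e-6  # enforce strict increase
        v = rng.uniform(0, 5, 50)
        expected = sum((t[i + 1] - t[i]) * (v[i] + v[i + 1]) / 2 for i in range(49))
        assert auc_trapezoid(t, v) == pytest.approx(expected, rel=1e-12)

    def test_matches_fine_riemann_on_smooth_curve(self):
        t = np.linspace(0, 12, 50)
        v = np.exp(-t / 3.0) * (1 + 0.5 * np.sin(t))
        tf = np.linspace(0, 12, 200001)
        riemann = np.sum(np.interp((tf[:-1] + tf[1:]) / 2, t, v)) * (tf[1] - tf[0])
        assert auc_trapezoid(t, v) == pytest.approx(riemann, rel=1e-8)


class TestAUCRatio:
    def test_equal_aucs_give_unity(self):
        assert auc_ratio(10.0, 10.0) == 1.0

    def test_arithmetic(self):
        assert auc_ratio(8.0, 10.0) == pytest.approx(0.8)

    def test_reciprocal_property(self):
        assert auc_ratio(3.7, 9.1) * auc_ratio(9.1, 3.7) == pytest.approx(1.0)

    def test_zero_data_auc_rejected(self):
        with pytest.raises(DataError):
            auc_ratio(1.0, 0.0)


class TestMSSD:
    def _sim(self):
        t = np.linspace(0, 10, 101)
        return (t, 2.0 * t)

    def test_exact_passthrough_is_zero(self):
        data = KineticDataset([1, 2, 3], [2, 4, 6], unit="mg/L")
        assert mssd(self._sim(), data) == pytest.approx(0.0, abs=1e-24)

    def test_unit_residuals(self):
        data = KineticDataset([1, 2], [2 + 1, 4 - 1], unit="mg/L")
        assert mssd(self._sim(), data) == pytest.approx(1.0)

    def test_ten_point_toy_matches_hand_arithmetic(self):
        t_sim = np.array([0.0, 2.0, 4.0, 6.0, 8.0, 10.0])
        v_sim = np.array([0.0, 1.0, 3.0, 2.0, 1.5, 0.5])
        t_obs = np.arange(0.5, 10.0, 1.0)  # 10 points between nodes
        obs = np.array([0.2, 0.9, 2.1, 3.0, 2.4, 2.1, 1.6, 1.4, 1.1, 0.3])
        pred = []
        for ti in t_obs:  # linear interpolation by hand
            j = int(ti // 2)
            frac = (ti - t_sim[j]) / 2.0
            pred.append(v_sim[j] + frac * (v_sim[j + 1] - v_sim[j]))
        expected = sum((p - o) ** 2 for p, o in zip(pred, obs)) / 10.0
        data = KineticDataset(t_obs, obs, unit="mg/L")
        assert mssd((t_sim, v_sim), data) == pytest.approx(expected, abs=1e-12)

    def test_unit_mismatch_is_an_error(self):
        data = KineticDataset([1, 2], [1, 2], unit="ppm")
        with pytest.raises(UnitError):
            mssd(self._sim(), data)

    def test_observation_outside_span_rejected(self):
        data = KineticDataset([1, 20], [1, 2], unit="mg/L")
        with pytest.raises(DataError):
            mssd(self._sim(), data)


class TestPerformanceErrors:
    def test_perfect_prediction(self):
        pe = performance_errors([1, 2, 3], [1, 2, 3])
        assert np.all(pe.pe_percent == 0)
        assert pe.mape_percent == pe.mpe_percent == pe.rmspe_percent == 0.0
        assert pe.r is not None  # non-constant series correlate perfectly
        assert pe.r == pytest.approx(1.0)

    def test_constant_series_flags_undefined_r(self):
        pe = performance_errors([2, 2, 2], [2, 2, 2])
        assert pe.r is None and "constant" in pe.r_note

    def test_pes_three_four_give_rmspe_sqrt_12_5(self):
        pe = performance_errors([100.0, 100.0], [103.0, 104.0])
        assert pe.rmspe_percent == pytest.approx(math.sqrt(12.5), rel=1e-12)

    def test_uniform_ten_percent_bias(self):
        meas = np.array([1.0, 2.0, 5.0, 9.0])
        pe = performance_errors(meas, 1.1 * meas)
        assert pe.mpe_percent == pytest.approx(10.0)
        assert pe.mape_percent == pytest.approx(10.0)
        assert pe.rmspe_percent == pytest.approx(10.0)
        assert pe.r == pytest.approx(1.0)

    def test_zero_measurement_error_names_the_point(self):
        with pytest.raises(DataError, match="index 1"):
            performance_errors([1.0, 0.0, 2.0], [1.0, 1.0, 2.0])

    def test_median_rmspe_variant(self):
        pe = performance_errors([100.0, 100.0, 100.0], [101.0, 102.0, 110.0],
                                median_rmspe=True)
        assert pe.rmspe_percent == pytest.approx(2.0)  # median of {1,4,100} squared errors

    def test_frozen_ten_point_fixture_to_1e12(self):
        meas = np.array([0.52, 1.13, 2.74, 3.60, 2.95, 2.31, 1.78, 1.22, 0.87, 0.41])
        pred = np.array([0.48, 1.25, 2.61, 3.88, 3.10, 2.12, 1.85, 1.09, 0.95, 0.37])
        pe_hand = [100.0 * (p - m) / m for m, p in zip(meas, pred)]
        mape_hand = float(np.median([abs(x) for x in pe_hand]))
        mpe_hand = float(np.median(pe_hand))
        rmspe_hand = math.sqrt(sum(x * x for x in pe_hand) / 10.0)
        pe = performance_errors(meas, pred)
        np.testing.assert_allclose(pe.pe_percent, pe_hand, rtol=1e-12)
        assert pe.mape_percent == pytest.approx(mape_hand, abs=1e-12)
        assert pe.mpe_percent == pytest.approx(mpe_hand, abs=1e-12)
        assert pe.rmspe_percent == pytest.approx(rmspe_hand, abs=1e-12)

    @given(st.permutations(range(8)))
    @settings(max_examples=40, deadline=None)
    def test_summaries_invariant_under_point_reordering(self, order):
        meas = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        pred = np.array([1.1, 1.8, 3.3, 4.4, 4.6, 6.9, 6.5, 8.8])
        a = performance_errors(meas, pred)
        b = performance_errors(meas[list(order)], pred[list(order)])
        assert a.mape_percent == pytest.approx(b.mape_percent, rel=1e-12)
        assert a.rmspe_percent == pytest.approx(b.rmspe_percent, rel=1e-12)

    @given(st.floats(min_value=1e-3, max_value=1e6))
    @settings(max_examples=40, deadline=None)
    def test_scale_invariance_of_pe_and_r(self, scale):
        # converting both series mg/L -> ng/mL must not change PE or r
        meas = np.array([1.0, 2.0, 3.5, 5.0])
        pred = np.array([1.2, 1.9, 3.0, 5.5])
        a = performance_errors(meas, pred)
        b = performance_errors(meas * scale, pred * scale)
        np.testing.assert_allclose(a.pe_percent, b.pe_percent, rtol=1e-9)
        assert a.r == pytest.approx(b.r, rel=1e-9)


class TestSensitivityRatio:
    def test_decoupled_parameter_gives_zero(self):
        run = lambda p: {"y": 42.0}
        assert sensitivity_ratio(run, {"x": 3.0}, "x", "y") == 0.0

    def test_linear_map_gives_unity(self):
        run = lambda p: {"y": 5.0 * p["x"]}
        assert sensitivity_ratio(run, {"x": 2.0}, "x", "y") == pytest.approx(1.0, rel=1e-9)

    def test_reciprocal_map_at_one_percent(self):
        run = lambda p: {"y": 3.0 / p["x"]}
        sr = sensitivity_ratio(run, {"x": 2.0}, "x", "y", delta=0.01)
        expected = (1.0 / 1.01 - 1.0) / 0.01  # -0.990099...
        assert sr == pytest.approx(expected, abs=1e-9)
        assert sr == pytest.approx(-0.990, abs=1e-3)

    def test_central_variant_agrees_within_order_delta(self):
        run = lambda p: {"y": p["x"] ** 2}
        fwd = sensitivity_ratio(run, {"x": 1.5}, "x", "y", delta=0.01)
        ctr = sensitivity_ratio(run, {"x": 1.5}, "x", "y", delta=0.01, central=True)
        assert ctr == pytest.approx(2.0, abs=1e-3)
        assert abs(fwd - ctr) < 0.05

    def test_zero_baseline_rejected(self):
        run = lambda p: {"y": 0.0}
        with pytest.raises(DataError):
            sensitivity_ratio(run, {"x": 1.0}, "x", "y")


class TestSensitivityScreen:
    def test_full_cross_sorted_by_magnitude(self):
        run = lambda p: {"a": 2 * p["x"] + 0 * p["z"], "b": 1.0 / p["y"]}
        report = sensitivity_screen(run, {"x": 1.0, "y": 2.0, "z": 3.0},
                                    ["x", "y", "z"], ["a", "b"])
        assert len(report.entries) + len(report.failures) == 6
        mags = [abs(e.sr) for e in report.entries]
        assert mags == sorted(mags, reverse=True)

    def test_individual_failures_recorded_not_fatal(self):
        def run(p):
            return {"good": p["x"], "bad": 0.0}
        report = sensitivity_screen(run, {"x": 1.0}, ["x"], ["good", "bad"])
        assert len(report.entries) == 1
        assert len(report.failures) == 1
        assert report.failures[0][:2] == ("x", "bad")
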