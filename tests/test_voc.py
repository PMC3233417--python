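"""Seven-compartment VOC model: structure, routes, kinetics, summaries."""

from dataclasses import replace

import numpy as np
import pytest

from pbpktk import engine, units, voc
from pbpktk.engine import SolverSettings, arterial_concentration, mass_balance_residual
from pbpktk.errors import ParameterError, ScenarioError
from pbpktk.evaluation import auc_trapezoid
from pbpktk.voc import (ExposureScenario, dermal_flux, hepatic_metabolism_rate,
                        oral_dose_events, peak_and_window_summary, simulate_voc)


class TestModelStructure:
    def test_seven_compartments_and_gas_exchange(self, tce, physiology):
        s = voc.build_voc_model(tce, physiology)
        assert {t.name for t in s.tissues} == set(voc.TISSUES)
        assert s.gas_exchange is not None
        rhs = engine.assemble_rhs(s)
        # blood + 6 tissues = the seven compartments; gut pool on top
        assert set(rhs.body_states) == set(voc.TISSUES) | {"venous_blood", "gut_lumen"}

    def test_metabolism_attached_to_liver_only(self, tce, physiology):
        s = voc.build_voc_model(tce, physiology)
        assert s.metabolism.compartment == "liver"

    def test_tissue_flows_close_to_cardiac_output(self, tce, physiology):
        s = voc.build_voc_model(tce, physiology)
        assert sum(t.flow_L_per_h for t in s.tissues) == pytest.approx(
            physiology.cardiac_output_L_per_h, rel=1e-12)

    @pytest.mark.parametrize("chem_id", ["BEN", "CCl4", "DCM", "VC"])
    def test_skin_partition_substituted_from_tce(self, chem_id, tce):
        chem = voc.load_voc_parameters(chem_id)
        assert "skin" in chem.substituted_partitions
        assert chem.partition("skin") == tce.partition("skin")

    def test_measured_skin_partitions_not_substituted(self):
        for chem_id in ("TCE", "PCE"):
            assert voc.load_voc_parameters(chem_id).substituted_partitions == {}

    def test_missing_partition_names_the_symbol(self, tce, physiology):
        partitions = {t: tce.partition(t) for t in voc.TISSUES if t != "liver"}
        broken = replace(tce, tissue_blood_partitions=partitions)
        with pytest.raises(ParameterError, match="liver"):
            voc.build_voc_model(broken, physiology)


class TestArterialConcentration:
    def test_zero_in_zero_out(self):
        assert arterial_concentration(0.0, 0.0, 348, 300, 9.5) == 0.0

    def test_no_ventilation_returns_venous(self):
        assert arterial_concentration(0.1, 5.0, 348, 0.0, 9.5) == pytest.approx(0.1)

    def test_hand_evaluated_quotient(self):
        got = arterial_concentration(0.1, 0.005374, 348, 300, 9.5)
        expected = (348 * 0.1 + 300 * 0.005374) / (348 + 300 / 9.5)
        assert got == pytest.approx(expected, rel=1e-12)


class TestHepaticMetabolism:
    def test_zero_concentration_zero_rate(self):
        assert hepatic_metabolism_rate(0.0, 5.0, 100.0, 1.0) == 0.0

    def test_half_saturation(self):
        # Cv = Km -> saturable part = Vmax/2
        assert hepatic_metabolism_rate(5.0, 5.0, 100.0, 1.0) == pytest.approx(50.0)

    def test_saturation_limit(self):
        rate = hepatic_metabolism_rate(1e4 * 5.0, 5.0, 100.0, 1.0)
        assert rate == pytest.approx(100.0, rel=1e-4)

    def test_first_order_pathway_adds_linearly(self):
        rate = hepatic_metabolism_rate(2.0, 2.0, 0.0, 1.0, k_first_order=0.5, v_liver_L=1.8)
        assert rate == pytest.approx(0.5 * 1.0 * 1.8)


class TestOralDosing:
    def test_four_bouts_of_equal_mass(self):
        events = oral_dose_events(0.05, 4, 70.0, 24.0)
        assert [e.time_h for e in events] == [0.0, 6.0, 12.0, 18.0]
        assert all(e.amount_mg == pytest.approx(0.875) for e in events)

    def test_single_bout_carries_full_daily_dose(self):
        (event,) = oral_dose_events(0.2, 1, 70.0, 24.0)
        assert event.amount_mg == pytest.approx(0.2 * 70.0, abs=1e-12)

    def test_daily_total_is_exact(self):
        events = oral_dose_events(0.123, 7, 81.0, 24.0)
        assert sum(e.amount_mg for e in events) == pytest.approx(0.123 * 81.0, abs=1e-12)

    def test_zero_body_weight_rejected(self):
        with pytest.raises(ParameterError):
            oral_dose_events(0.05, 4, 0.0, 24.0)

    def test_absorbed_equals_administered(self, tce, physiology, quick_settings):
        sc = ExposureScenario(duration_h=72.0, oral_mg_per_kg_day=0.05)
        res = simulate_voc(tce, physiology, sc, quick_settings)
        administered = res.ledger["oral_intake"][-1]
        assert administered == pytest.approx(0.05 * physiology.body_weight_kg * 3, abs=1e-9)
        # gut holds only the tail of the last bolus (6 h of first-order emptying)
        per_bolus = 0.05 * physiology.body_weight_kg / 4
        tails = sum(per_bolus * np.exp(-(72.0 - t) * tce.oral_ka_per_h)
                    for t in np.arange(0.0, 72.0, 6.0))
        assert res.amounts["gut_lumen"][-1] == pytest.approx(tails, rel=1e-5)
        assert mass_balance_residual(res) < 1e-6


class TestDermalRoute:
    def test_zero_gradient_zero_flux(self):
        assert dermal_flux(0.15, 1000.0, 0.0, 0.0, 4.0) == 0.0
        assert dermal_flux(0.15, 1000.0, 1.0, 4.0, 4.0) == 0.0  # equilibrium

    def test_flux_linear_in_area(self):
        f1 = dermal_flux(0.15, 1000.0, 1.0, 0.0, 4.0)
        f2 = dermal_flux(0.15, 2000.0, 1.0, 0.0, 4.0)
        assert f2 == pytest.approx(2 * f1)

    def test_missing_kp_is_an_explicit_error(self, physiology):
        ben = voc.load_voc_parameters("BEN")
        sc = ExposureScenario(duration_h=8.0, dermal=[(0.0, 1.0, 0.5, 18000.0)])
        with pytest.raises(ParameterError, match="Kp"):
            voc.build_voc_model(ben, physiology, sc)

    def test_dermal_uptake_appears_in_ledger(self, tce, physiology, quick_settings):
        sc = ExposureScenario(duration_h=8.0, dermal=[(0.0, 2.0, 5.0, 18000.0)])
        res = simulate_voc(tce, physiology, sc, quick_settings)
        assert res.ledger["dermal_absorbed"][-1] > 0
        assert mass_balance_residual(res) < 1e-6


class TestScenarioValidation:
    def test_interval_outside_duration_rejected(self):
        with pytest.raises(ScenarioError):
            ExposureScenario(duration_h=10.0, inhalation_ppm=[(0.0, 12.0, 1.0)])

    def test_bout_times_must_increase(self):
        with pytest.raises(ScenarioError):
            ExposureScenario(duration_h=48.0, oral_mg_per_kg_day=0.1,
                             oral_bout_times_h=[0.0, 6.0, 6.0, 18.0], oral_bouts_per_day=4)


class TestSimulationPhysics:
    def test_zero_exposure_all_zero(self, tce, physiology, quick_settings):
        sc = ExposureScenario(duration_h=24.0)
        res = simulate_voc(tce, physiology, sc, quick_settings)
        for name, series in res.concentrations.items():
            assert np.all(series == 0.0), name

    def test_no_metabolism_steady_state_is_pb_times_cinh(self, tce_no_metabolism,
                                                         physiology, quick_settings):
        sc = ExposureScenario(duration_h=2000.0, inhalation_ppm=[(0.0, 2000.0, 1.0)])
        res = simulate_voc(tce_no_metabolism, physiology, sc, quick_settings)
        c_inh = units.ppm_to_mg_per_L(1.0, tce_no_metabolism.molecular_weight)
        expected = tce_no_metabolism.blood_air_partition * c_inh
        assert res.concentrations["venous_blood"][-1] == pytest.approx(expected, rel=5e-3)

    def test_equilibrium_tissue_ratios(self, tce_no_metabolism, physiology, quick_settings):
        sc = ExposureScenario(duration_h=2000.0, inhalation_ppm=[(0.0, 2000.0, 1.0)])
        res = simulate_voc(tce_no_metabolism, physiology, sc, quick_settings)
        c_art = res.concentrations["arterial_blood"][-1]
        for t in voc.TISSUES:
            expected = tce_no_metabolism.partition(t) * c_art
            assert res.concentrations[t][-1] == pytest.approx(expected, rel=5e-3), t

    def test_subsaturating_linearity_of_auc(self, tce, physiology, quick_settings):
        aucs = []
        for ppm in (0.001, 0.002):
            sc = ExposureScenario(duration_h=48.0, inhalation_ppm=[(0.0, 48.0, ppm)])
            res = simulate_voc(tce, physiology, sc, quick_settings)
            aucs.append(auc_trapezoid(res.time_h, res.concentrations["venous_blood"]))
        assert aucs[1] / aucs[0] == pytest.approx(2.0, rel=5e-3)

    def test_route_intake_ledgers_are_additive(self, tce, physiology, quick_settings):
        inh = ExposureScenario(duration_h=48.0, inhalation_ppm=[(0.0, 48.0, 0.2)])
        oral = ExposureScenario(duration_h=48.0, oral_mg_per_kg_day=0.05)
        both = ExposureScenario(duration_h=48.0, inhalation_ppm=[(0.0, 48.0, 0.2)],
                                oral_mg_per_kg_day=0.05)
        r_inh = simulate_voc(tce, physiology, inh, quick_settings)
        r_oral = simulate_voc(tce, physiology, oral, quick_settings)
        r_both = simulate_voc(tce, physiology, both, quick_settings)
        assert r_both.ledger["oral_intake"][-1] == pytest.approx(
            r_oral.ledger["oral_intake"][-1], abs=1e-12)
        assert r_both.ledger["inhaled_intake"][-1] == pytest.approx(
            r_inh.ledger["inhaled_intake"][-1], rel=1e-9)

    def test_metabolism_lowers_blood_auc(self, tce, tce_no_metabolism, physiology,
                                         quick_settings):
        sc = ExposureScenario(duration_h=48.0, inhalation_ppm=[(0.0, 48.0, 1.0)])
        auc_met = auc_trapezoid(*_blood(simulate_voc(tce, physiology, sc, quick_settings)))
        auc_off = auc_trapezoid(*_blood(simulate_voc(tce_no_metabolism, physiology, sc,
                                                     quick_settings)))
        assert auc_met < auc_off

    def test_uncited_parameter_set_refused_unless_synthetic(self, tce, physiology):
        sc = ExposureScenario(duration_h=1.0)
        uncited = replace(tce, citation=None)
        with pytest.raises(ParameterError, match="citation"):
            simulate_voc(uncited, physiology, sc)
        simulate_voc(replace(uncited, synthetic=True), physiology, sc)  # runs


def _blood(result):
    return result.time_h, result.concentrations["venous_blood"]


class TestPeakAndWindowSummary:
    def _result(self, times, values):
        from pbpktk.engine import SimulationResult
        return SimulationResult(time_h=np.asarray(times, float),
                                amounts={}, ledger={},
                                concentrations={"venous_blood": np.asarray(values, float)})

    def test_constant_series(self):
        t = np.linspace(0, 72, 721)
        s = peak_and_window_summary(self._result(t, np.full_like(t, 3.0)))
        assert s["peak_mg_per_L"] == 3.0
        assert s["steady_state_mean_mg_per_L"] == pytest.approx(3.0)
        assert s["steady_state_attained"] is True

    def test_monotone_rise_flags_non_attainment(self):
        t = np.linspace(0, 96, 961)
        s = peak_and_window_summary(self._result(t, t * 0.01))
        assert s["steady_state_attained"] is False

    def test_triangular_pulse_peak_is_apex(self):
        t = np.linspace(0, 48, 481)
        v = np.interp(t, [0, 10, 48], [0, 7.5, 0])
        s = peak_and_window_summary(self._result(t, v))
        assert s["peak_mg_per_L"] == pytest.approx(7.5)
        assert s["t_peak_h"] == pytest.approx(10.0)

    def test_short_run_marks_steady_state_unavailable(self):
        t = np.linspace(0, 12, 121)
        s = peak_and_window_summary(self._result(t, np.ones_like(t)))
        assert s["steady_state_mean_mg_per_L"] is None
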