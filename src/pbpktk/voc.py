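"""Generic seven-compartment VOC PBPK model.

Compartments: venous blood, fat, skin, kidney, liver, rapidly perfused and
slowly perfused tissue, plus a steady-state gas-exchange (lung) step.
Routes: inhalation (ppm schedule through the lung), oral (boluses into a
gut-lumen pool absorbed first-order into liver inflow, so oral doses see
hepatic first pass), and dermal (permeability-limited flux from water into
the skin compartment).  Metabolism is saturable (Michaelis-Menten, with an
optional parallel first-order pathway) and attached to the liver only.

Bundled parameter sets cover BEN, CCl4, DCM, PCE, TCE and VC.  Only TCE and
PCE have measured human skin:blood partitions; for the others the TCE value
is substituted and the substitution is logged and recorded in the result
metadata.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from . import engine, units
from .engine import (BolusEvent, FlowLimitedStructure, GasExchangeSpec,
                     MetabolismSpec, PhysiologySpec, SimulationResult,
                     SolverSettings, Source, TissueSpec, Transfer,
                     arterial_concentration)
from .errors import ParameterError, ScenarioError

log = logging.getLogger(__name__)

TISSUES = ("fat", "skin", "kidney", "liver", "rapid", "slow")
BUNDLED_CHEMICALS = ("BEN", "CCl4", "DCM", "PCE", "TCE", "VC")

#: Metabolic capacity scales allometrically: Vmax = vmax_c * BW^0.75.
VMAX_BW_EXPONENT = 0.75


@dataclass(frozen=True)
class VOCParameterSet:
    """Physicochemical and metabolic constants for one volatile."""

    chemical: str
    molecular_weight: float
    blood_air_partition: float
    tissue_blood_partitions: Mapping[str, float]
    vmax_c: float  # mg/h per kg^0.75
    km: float  # mg/L
    k_first_order_per_h: float = 0.0
    oral_ka_per_h: float = 1.0
    dermal_kp_cm_per_h: float | None = None
    skin_water_partition: float | None = None
    citation: str | None = None
    synthetic: bool = False
    name: str = ""
    substituted_partitions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.molecular_weight <= 0:
            raise ParameterError(f"{self.chemical}: molecular weight must be positive")
        if self.blood_air_partition <= 0:
            raise ParameterError(f"{self.chemical}: blood:air partition must be positive")
        for t, p in self.tissue_blood_partitions.items():
            if not (p > 0):
                raise ParameterError(f"{self.chemical}: partition for {t!r} must be positive")
        if self.vmax_c < 0 or self.k_first_order_per_h < 0:
            raise ParameterError(f"{self.chemical}: metabolic rates must be non-negative")
        if self.vmax_c > 0 and self.km <= 0:
            raise ParameterError(f"{self.chemical}: Km must be positive when Vmax > 0")
        if self.oral_ka_per_h <= 0:
            raise ParameterError(f"{self.chemical}: oral ka must be positive")

    def partition(self, tissue: str) -> float:
        try:
            return self.tissue_blood_partitions[tissue]
        except KeyError:
            raise ParameterError(
                f"{self.chemical}: missing tissue:blood partition coefficient for {tissue!r}"
            ) from None

    def vmax_mg_per_h(self, body_weight_kg: float) -> float:
        return self.vmax_c * body_weight_kg ** VMAX_BW_EXPONENT


def _data_text(relpath: str) -> str:
    return resources.files("pbpktk.data").joinpath(relpath).read_text()


def load_voc_parameters(chemical: str) -> VOCParameterSet:
    """Load a bundled chemical, filling a missing skin partition from TCE.

    The substitution (made because only TCE and PCE human skin:blood
    partitions have been measured) is logged and recorded on the returned
    parameter set.
    """
    chem = chemical.upper().replace("CL4", "Cl4")
    if chem not in BUNDLED_CHEMICALS:
        raise ParameterError(f"unknown chemical {chemical!r}; bundled: {BUNDLED_CHEMICALS}")
    raw = json.loads(_data_text(f"voc/{chem.lower()}.json"))
    partitions = dict(raw["tissue_blood_partitions"])
    substituted = {}
    if "skin" not in partitions:
        tce = json.loads(_data_text("voc/tce.json"))
        partitions["skin"] = tce["tissue_blood_partitions"]["skin"]
        substituted["skin"] = "skin:blood partition not measured for this chemical; TCE value substituted"
        log.warning("%s: %s (P_skin=%s)", chem, substituted["skin"], partitions["skin"])
    return VOCParameterSet(
        chemical=raw["chemical"],
        name=raw.get("name", ""),
        molecular_weight=raw["molecular_weight_g_per_mol"],
        blood_air_partition=raw["blood_air_partition"],
        tissue_blood_partitions=partitions,
        vmax_c=raw["vmax_c_mg_per_h_kg075"],
        km=raw["km_mg_per_L"],
        k_first_order_per_h=raw.get("k_first_order_per_h", 0.0),
        oral_ka_per_h=raw.get("oral_ka_per_h", 1.0),
        dermal_kp_cm_per_h=raw.get("dermal_kp_cm_per_h"),
        skin_water_partition=raw.get("skin_water_partition"),
        citation=raw.get("citation"),
        substituted_partitions=substituted,
    )


def load_default_physiology() -> PhysiologySpec:
    raw = json.loads(_data_text("physiology/adult_default.json"))
    return PhysiologySpec(
        body_weight_kg=raw["body_weight_kg"],
        cardiac_output_L_per_h=raw["cardiac_output_L_per_h"],
        alveolar_ventilation_L_per_h=raw["alveolar_ventilation_L_per_h"],
        volume_fractions=raw["volume_fractions"],
        flow_fractions=raw["flow_fractions"],
    )


@dataclass(frozen=True)
class ExposureScenario:
    """Multi-route, time-structured exposure over ``duration_h`` hours.

    * inhalation: (start_h, end_h, ppm) intervals;
    * oral: a daily mg/kg-day rate split into equal boluses at
      ``oral_bout_times_h`` within each day;
    * dermal: (start_h, end_h, water mg/L, exposed area cm^2) intervals.
    """

    duration_h: float
    inhalation_ppm: Sequence[tuple[float, float, float]] = ()
    oral_mg_per_kg_day: float = 0.0
    oral_bouts_per_day: int = 4
    oral_bout_times_h: Sequence[float] | None = None
    dermal: Sequence[tuple[float, float, float, float]] = ()
    scenario_id: str = ""

    def __post_init__(self):
        if self.duration_h <= 0:
            raise ScenarioError("duration must be positive")
        for s, e, ppm in self.inhalation_ppm:
            if not (0 <= s < e <= self.duration_h):
                raise ScenarioError(f"inhalation interval [{s}, {e}] outside [0, {self.duration_h}]")
            if ppm < 0:
                raise ScenarioError("inhalation concentration must be non-negative")
        if self.oral_mg_per_kg_day < 0:
            raise ScenarioError("oral dose rate must be non-negative")
        if self.oral_bouts_per_day < 1:
            raise ScenarioError("need at least one oral bout per day")
        times = self.bout_times()
        if any(not 0 <= t < 24 for t in times) or any(b <= a for a, b in zip(times, times[1:])):
            raise ScenarioError("bout times must be strictly increasing within [0, 24) h")
        for s, e, cw, area in self.dermal:
            if not (0 <= s < e <= self.duration_h):
                raise ScenarioError(f"dermal interval [{s}, {e}] outside [0, {self.duration_h}]")
            if cw < 0 or area < 0:
                raise ScenarioError("dermal concentration and area must be non-negative")

    def bout_times(self) -> tuple[float, ...]:
        if self.oral_bout_times_h is not None:
            return tuple(float(t) for t in self.oral_bout_times_h)
        step = 24.0 / self.oral_bouts_per_day
        return tuple(i * step for i in range(self.oral_bouts_per_day))

    def inhaled_mg_per_L(self, molecular_weight: float):
        """Step function t -> inhaled air concentration in mg/L."""
        ivals = [(s, e, units.ppm_to_mg_per_L(ppm, molecular_weight))
                 for s, e, ppm in self.inhalation_ppm]

        def f(t: float) -> float:
            for s, e, c in ivals:
                if s <= t <= e:
                    return c
            return 0.0

        return f

    def breakpoints(self) -> list[float]:
        cuts = set()
        for s, e, _ in self.inhalation_ppm:
            cuts.update((s, e))
        for s, e, _, _ in self.dermal:
            cuts.update((s, e))
        return sorted(cuts)


def oral_dose_events(dose_rate_mg_per_kg_day: float, bouts_per_day: int,
                     body_weight_kg: float, duration_h: float,
                     bout_times_h: Sequence[float] | None = None) -> list[BolusEvent]:
    """Split a daily oral rate into equal gut-lumen boluses.

    The bolus mass is dose*BW/bouts, so the boluses of one day always sum
    to the full daily dose.
    """
    if body_weight_kg <= 0:
        raise ParameterError("body weight must be positive")
    if bouts_per_day < 1:
        raise ScenarioError("need at least one oral bout per day")
    if bout_times_h is None:
        step = 24.0 / bouts_per_day
        bout_times_h = [i * step for i in range(bouts_per_day)]
    per_bolus = dose_rate_mg_per_kg_day * body_weight_kg / bouts_per_day
    events = []
    day = 0
    while day * 24.0 < duration_h:
        for bt in bout_times_h:
            t = day * 24.0 + bt
            if t < duration_h and per_bolus > 0:
                events.append(BolusEvent(time_h=t, target="gut_lumen",
                                         amount_mg=per_bolus, ledger="oral_intake"))
        day += 1
    return events


def hepatic_metabolism_rate(c_liver: float, p_liver: float, vmax: float, km: float,
                            k_first_order: float = 0.0, v_liver_L: float = 1.0) -> float:
    """Michaelis-Menten + optional first-order hepatic clearance (mg/h).

    Operates on the venous-equilibrium concentration Cv = C_liver/P_liver.
    """
    cv = c_liver / p_liver
    rate = k_first_order * cv * v_liver_L
    if vmax > 0:
        rate += vmax * cv / (km + cv)
    return rate


def dermal_flux(kp_cm_per_h: float, area_cm2: float, c_water_mg_per_L: float,
                c_skin_mg_per_L: float, skin_water_partition: float) -> float:
    """Permeability-limited flux (mg/h) from water into skin.

    flux = Kp * A * (C_water - C_skin / P_skin:water) * 1e-3 L/cm^3; may be
    negative when the skin desorbs back into clean water.
    """
    if kp_cm_per_h is None:
        raise ParameterError("dermal permeability Kp is not available for this chemical")
    if skin_water_partition is None or skin_water_partition <= 0:
        raise ParameterError("skin:water partition is not available for this chemical")
    gradient = c_water_mg_per_L - c_skin_mg_per_L / skin_water_partition
    return kp_cm_per_h * area_cm2 * 1e-3 * gradient


def build_voc_model(chemical: VOCParameterSet, physiology: PhysiologySpec,
                    scenario: ExposureScenario | None = None) -> FlowLimitedStructure:
    """Assemble the seven-compartment structure for one chemical.

    Metabolism is attached to the liver only; oral absorption feeds the
    liver from a gut-lumen pool; dermal flux (if the scenario asks for it)
    feeds the skin compartment.
    """
    tissues = [TissueSpec(name=t, volume_L=physiology.volume_L(t),
                          flow_L_per_h=physiology.flow_L_per_h(t),
                          partition=chemical.partition(t))
               for t in TISSUES]

    inhaled = (scenario.inhaled_mg_per_L(chemical.molecular_weight)
               if scenario is not None else (lambda t: 0.0))
    sources: list[Source] = []
    if scenario is not None and scenario.dermal:
        if chemical.dermal_kp_cm_per_h is None:
            raise ParameterError(
                f"{chemical.chemical}: dermal exposure requested but no Kp (permeability "
                "constant) is available for this chemical")
        if chemical.skin_water_partition is None:
            raise ParameterError(
                f"{chemical.chemical}: dermal exposure requested but no skin:water "
                "partition is available for this chemical")
        kp = chemical.dermal_kp_cm_per_h
        psw = chemical.skin_water_partition
        intervals = tuple(scenario.dermal)

        def dermal_rate(t, conc, _kp=kp, _psw=psw, _iv=intervals):
            for s, e, cw, area in _iv:
                if s <= t <= e:
                    return dermal_flux(_kp, area, cw, conc["skin"], _psw)
            return 0.0

        sources.append(Source(target="skin", ledger="dermal_absorbed", rate=dermal_rate))

    return FlowLimitedStructure(
        tissues=tissues,
        blood_volume_L=physiology.volume_L("blood"),
        cardiac_output_L_per_h=physiology.cardiac_output_L_per_h,
        gas_exchange=GasExchangeSpec(
            alveolar_ventilation_L_per_h=physiology.alveolar_ventilation_L_per_h,
            blood_air_partition=chemical.blood_air_partition,
            inhaled_mg_per_L=inhaled),
        pools=("gut_lumen",),
        transfers=(Transfer("gut_lumen", "liver", chemical.oral_ka_per_h),),
        sources=tuple(sources),
        metabolism=MetabolismSpec(
            compartment="liver",
            vmax_mg_per_h=chemical.vmax_mg_per_h(physiology.body_weight_kg),
            km_mg_per_L=chemical.km if chemical.vmax_c > 0 else 1.0,
            first_order_per_h=chemical.k_first_order_per_h),
        extra_ledgers=("oral_intake",),
        name=f"voc:{chemical.chemical}",
    )


def simulate_voc(chemical: VOCParameterSet, physiology: PhysiologySpec,
                 scenario: ExposureScenario,
                 settings: SolverSettings = SolverSettings()) -> SimulationResult:
    """Run one chemical through an exposure scenario.

    Parameter sets lacking a source citation are refused unless explicitly
    marked ``synthetic`` (screening results must carry provenance).
    """
    if chemical.citation is None and not chemical.synthetic:
        raise ParameterError(
            f"{chemical.chemical}: parameter set has no source citation; mark it "
            "synthetic=True to run it as a non-fidelity set")
    structure = build_voc_model(chemical, physiology, scenario)
    rhs = engine.assemble_rhs(structure)
    events = oral_dose_events(scenario.oral_mg_per_kg_day, scenario.oral_bouts_per_day,
                              physiology.body_weight_kg, scenario.duration_h,
                              scenario.oral_bout_times_h)
    result = engine.integrate(rhs, None, scenario.duration_h, settings,
                              events=events, breakpoints=scenario.breakpoints(),
                              metadata={
                                  "chemical": chemical.chemical,
                                  "scenario_id": scenario.scenario_id,
                                  "citation": chemical.citation,
                                  "substitutions": dict(chemical.substituted_partitions),
                                  "body_weight_kg": physiology.body_weight_kg,
                              })
    return result


def peak_and_window_summary(result: SimulationResult, series: str = "venous_blood",
                            window_h: float = 24.0, trend_tol: float = 0.01) -> dict:
    """Peak, time of peak, AUC, and steady-state mean over the last 24 h.

    The steady-state mean is flagged unattained when the last-window mean
    still drifts by more than ``trend_tol`` (1 %/day default) relative to
    the preceding window; for runs shorter than the window it is marked
    unavailable.
    """
    t = result.time_h
    if len(t) == 0:
        raise ValueError("empty simulation result")
    c = result.series(series)
    i_peak = int(np.argmax(c))
    summary = {
        "series": series,
        "peak_mg_per_L": float(c[i_peak]),
        "peak_ng_per_mL": float(units.mg_per_L_to_ng_per_mL(c[i_peak])),
        "t_peak_h": float(t[i_peak]),
        "auc_mg_h_per_L": float(np.trapezoid(c, t)),
    }
    if t[-1] - t[0] < window_h:
        summary.update(steady_state_mean_mg_per_L=None, steady_state_attained=None,
                       steady_state_note="duration shorter than averaging window")
        return summary
    last = c[t >= t[-1] - window_h]
    ss_mean = float(np.mean(last))
    summary["steady_state_mean_mg_per_L"] = ss_mean
    summary["steady_state_mean_ng_per_mL"] = units.mg_per_L_to_ng_per_mL(ss_mean)
    if t[-1] - t[0] >= 2 * window_h:
        prev = c[(t >= t[-1] - 2 * window_h) & (t < t[-1] - window_h)]
        prev_mean = float(np.mean(prev))
        drift = abs(ss_mean - prev_mean) / ss_mean if ss_mean > 0 else 0.0
        summary["steady_state_attained"] = bool(drift <= trend_tol)
        summary["window_drift_fraction"] = drift
    else:
        summary["steady_state_attained"] = None
    return summary
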