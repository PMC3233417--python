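"""Adapters exposing model inputs as flat parameter maps for SR screens.

A runner maps a dict of perturbable inputs to a dict of scalar outputs by
re-simulating the model; :func:`pbpktk.evaluation.sensitivity_ratio`
perturbs one input at a time through it.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping

import numpy as np

from . import voc
from .engine import PhysiologySpec, SolverSettings
from .evaluation import auc_trapezoid

#: perturbable VOC inputs: how to fold the value back into chemical/physiology
_CHEM_KEYS = ("vmax_c", "km", "blood_air_partition", "k_first_order_per_h", "oral_ka_per_h")
_PHYS_KEYS = ("alveolar_ventilation", "cardiac_output", "body_weight")
_PARTITION_PREFIX = "partition_"  # e.g. partition_fat


def voc_runner(chemical, scenario: voc.ExposureScenario,
               physiology: PhysiologySpec | None = None,
               settings: SolverSettings | None = None,
               series: str = "venous_blood"):
    """Build (run, baseline_params) for a VOC sensitivity screen.

    Outputs: ``blood_auc`` (mg*h/L), ``peak`` (mg/L) and
    ``steady_state_mean`` (mg/L, when the run is long enough).
    """
    if isinstance(chemical, str):
        chemical = voc.load_voc_parameters(chemical)
    phys = physiology or voc.load_default_physiology()
    # a slightly looser tolerance than the default keeps SR screens quick
    settings = settings or SolverSettings(rtol=1e-8, atol=1e-10)

    params: dict[str, float] = {
        "vmax_c": chemical.vmax_c,
        "km": chemical.km,
        "blood_air_partition": chemical.blood_air_partition,
        "oral_ka_per_h": chemical.oral_ka_per_h,
        "alveolar_ventilation": phys.alveolar_ventilation_L_per_h,
        "cardiac_output": phys.cardiac_output_L_per_h,
        "body_weight": phys.body_weight_kg,
    }
    if chemical.k_first_order_per_h:
        params["k_first_order_per_h"] = chemical.k_first_order_per_h
    for t, p in chemical.tissue_blood_partitions.items():
        params[f"{_PARTITION_PREFIX}{t}"] = p

    def run(p: Mapping[str, float]) -> dict[str, float]:
        partitions = dict(chemical.tissue_blood_partitions)
        chem_kwargs = {}
        phys_kwargs = {}
        for key, value in p.items():
            if key in _CHEM_KEYS:
                chem_kwargs[key] = value
            elif key == "alveolar_ventilation":
                phys_kwargs["alveolar_ventilation_L_per_h"] = value
            elif key == "cardiac_output":
                phys_kwargs["cardiac_output_L_per_h"] = value
            elif key == "body_weight":
                phys_kwargs["body_weight_kg"] = value
            elif key.startswith(_PARTITION_PREFIX):
                partitions[key[len(_PARTITION_PREFIX):]] = value
            else:
                raise KeyError(f"unknown perturbable input {key!r}")
        chem = replace(chemical, tissue_blood_partitions=partitions, **chem_kwargs)
        ph = PhysiologySpec(
            body_weight_kg=phys_kwargs.get("body_weight_kg", phys.body_weight_kg),
            cardiac_output_L_per_h=phys_kwargs.get("cardiac_output_L_per_h",
                                                   phys.cardiac_output_L_per_h),
            alveolar_ventilation_L_per_h=phys_kwargs.get("alveolar_ventilation_L_per_h",
                                                         phys.alveolar_ventilation_L_per_h),
            volume_fractions=phys.volume_fractions,
            flow_fractions=phys.flow_fractions)
        result = voc.simulate_voc(chem, ph, scenario, settings)
        c = result.series(series)
        out = {"blood_auc": auc_trapezoid(result.time_h, c), "peak": float(np.max(c))}
        summary = voc.peak_and_window_summary(result, series=series)
        if summary.get("steady_state_mean_mg_per_L") is not None:
            out["steady_state_mean"] = summary["steady_state_mean_mg_per_L"]
        return out

    return run, params
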