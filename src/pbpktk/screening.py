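"""MRL exposure scenarios and biomonitoring screening.

The screening workflow builds worst-case exposure scenarios at a
chemical's Minimal Risk Levels -- continuous 24 h/day inhalation at the
ppm MRL combined with the oral MRL split into four equally spaced daily
drinking bouts, for the MRL's duration class (acute 14 days; intermediate
365 days; chronic simulated as 365 days with a steady-state attainment
flag) -- simulates the resulting blood concentration, and compares
biomonitoring measurements against the predicted screening level: a
measured level below the prediction is regarded as consistent with
exposures below the MRL.

The module also provides a deterministic synthetic-fixture generator whose
reduced models carry their own closed-form reference values, used by the
test-suite and available from the CLI.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import engine, units, voc
from .engine import PhysiologySpec, SolverSettings
from .errors import ConfigError, DataError, ScenarioError, UnitError
from .voc import ExposureScenario, VOCParameterSet

log = logging.getLogger(__name__)

DURATION_HOURS = {"acute": 14 * 24.0, "intermediate": 365 * 24.0, "chronic": 365 * 24.0}

BELOW = "below-screening-level"
EXCEEDS = "exceeds-screening-level"
INDETERMINATE = "indeterminate-LOD"


@dataclass(frozen=True)
class MRLEntry:
    """Minimal Risk Levels for one chemical and duration class."""

    chemical: str
    inhalation_ppm: float | None
    oral_mg_per_kg_day: float | None
    duration_class: str

    def __post_init__(self):
        if self.duration_class not in DURATION_HOURS:
            raise ScenarioError(f"unknown duration class {self.duration_class!r}")
        if self.inhalation_ppm is None and self.oral_mg_per_kg_day is None:
            raise ScenarioError(f"{self.chemical}: MRL entry must carry at least one route")
        for v in (self.inhalation_ppm, self.oral_mg_per_kg_day):
            if v is not None and v <= 0:
                raise ScenarioError(f"{self.chemical}: MRL values must be positive")


def load_mrl_table() -> list[MRLEntry]:
    raw = json.loads(resources.files("pbpktk.data").joinpath("screening/mrl_table.json").read_text())
    return [MRLEntry(chemical=e["chemical"], inhalation_ppm=e.get("inhalation_ppm"),
                     oral_mg_per_kg_day=e.get("oral_mg_per_kg_day"),
                     duration_class=e["duration_class"]) for e in raw["entries"]]


def build_mrl_scenario(entry: MRLEntry,
                       bout_times_h: Sequence[float] = (0.0, 6.0, 12.0, 18.0)) -> ExposureScenario:
    """Continuous inhalation + 4 equal daily oral bouts at the MRLs."""
    duration = DURATION_HOURS[entry.duration_class]
    inhalation = ([(0.0, duration, entry.inhalation_ppm)]
                  if entry.inhalation_ppm is not None else [])
    return ExposureScenario(
        duration_h=duration,
        inhalation_ppm=inhalation,
        oral_mg_per_kg_day=entry.oral_mg_per_kg_day or 0.0,
        oral_bouts_per_day=len(bout_times_h),
        oral_bout_times_h=tuple(bout_times_h),
        scenario_id=f"MRL:{entry.chemical}:{entry.duration_class}",
    )


@dataclass(frozen=True)
class BiomonitoringRow:
    analyte: str
    statistic: str
    value: float | None  # None for "<LOD"
    ci_low: float | None
    ci_high: float | None
    lod: float | None
    unit: str
    stratum: str = ""

    def __post_init__(self):
        if self.value is None and self.lod is None:
            raise DataError(f"{self.analyte}: below-LOD row must carry the LOD")
        if self.value is not None and self.lod is not None and self.value < self.lod:
            raise DataError(f"{self.analyte}: measured value {self.value} below LOD {self.lod} "
                            "must be flagged '<LOD'")


def load_biomonitoring_table(path: str | Path | None = None) -> list[BiomonitoringRow]:
    """Read a biomonitoring CSV (defaults to the bundled NHANES VOC table)."""
    if path is None:
        with resources.as_file(resources.files("pbpktk.data")
                               .joinpath("screening/nhanes_2003_2004_voc.csv")) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    rows = []
    for _, r in df.iterrows():
        def num(x):
            return None if pd.isna(x) else float(x)
        rows.append(BiomonitoringRow(analyte=r["analyte"], statistic=str(r["statistic"]),
                                     value=num(r.get("value")), ci_low=num(r.get("ci_low")),
                                     ci_high=num(r.get("ci_high")), lod=num(r.get("lod")),
                                     unit=str(r["unit"]), stratum=str(r.get("stratum", ""))))
    return rows


@dataclass(frozen=True)
class ScreeningVerdict:
    analyte: str
    predicted: float
    measured: float | None
    lod: float | None
    unit: str
    verdict: str
    margin: float | None  # predicted / measured (or predicted / LOD)
    note: str = ""


def screen_against_biomonitoring(predictions_ng_per_mL: Mapping[str, float],
                                 table: Sequence[BiomonitoringRow],
                                 unit: str = "ng/mL") -> list[ScreeningVerdict]:
    """Compare measured biomonitoring levels to predicted screening levels.

    measured < predicted -> below-screening-level (exposure consistent with
    less than the MRL); measured >= predicted -> exceeds-screening-level;
    for "<LOD" rows the LOD is compared instead: LOD < predicted means the
    population is below the screening level (annotated as LOD-based),
    otherwise the row is indeterminate.
    """
    verdicts = []
    for row in table:
        if row.analyte not in predictions_ng_per_mL:
            continue
        if row.unit.replace(" ", "") != unit.replace(" ", ""):
            raise UnitError(f"{row.analyte}: biomonitoring unit {row.unit!r} != {unit!r}")
        pred = float(predictions_ng_per_mL[row.analyte])
        if row.value is not None:
            verdict = BELOW if row.value < pred else EXCEEDS
            margin = pred / row.value if row.value > 0 else None
            note = ""
            measured = row.value
        else:
            measured = None
            if row.lod < pred:
                verdict, note = BELOW, "measured <LOD; LOD below predicted screening level"
            else:
                verdict, note = INDETERMINATE, "measured <LOD but LOD exceeds predicted level"
            margin = pred / row.lod if row.lod and row.lod > 0 else None
        verdicts.append(ScreeningVerdict(analyte=row.analyte, predicted=pred,
                                         measured=measured, lod=row.lod, unit=unit,
                                         verdict=verdict, margin=margin, note=note))
    return verdicts


def run_mrl_screen(chemicals: Sequence[str] | None = None,
                   physiology: PhysiologySpec | None = None,
                   settings: SolverSettings | None = None,
                   table: Sequence[BiomonitoringRow] | None = None):
    """Simulate every MRL entry and screen it against the biomonitoring table.

    Returns (summaries, verdicts): per-chemical peak/steady-state summaries
    (both mg/L and ng/mL) and the verdict rows.
    """
    phys = physiology or voc.load_default_physiology()
    settings = settings or SolverSettings()
    table = table if table is not None else load_biomonitoring_table()
    entries = load_mrl_table()
    if chemicals is not None:
        wanted = {c.upper().replace("CL4", "Cl4") for c in chemicals}
        entries = [e for e in entries if e.chemical in wanted]
    summaries = {}
    for entry in entries:
        chem = voc.load_voc_parameters(entry.chemical)
        scenario = build_mrl_scenario(entry)
        result = voc.simulate_voc(chem, phys, scenario, settings)
        s = voc.peak_and_window_summary(result)
        s["duration_class"] = entry.duration_class
        s["mass_balance_residual"] = engine.mass_balance_residual(result)
        s["substitutions"] = result.metadata.get("substitutions", {})
        summaries[entry.chemical] = s
    predictions = {c: s["peak_ng_per_mL"] for c, s in summaries.items()}
    verdicts = screen_against_biomonitoring(predictions, table)
    return summaries, verdicts


# -- synthetic fixtures ----------------------------------------------------

@dataclass(frozen=True)
class SyntheticFixture:
    """A randomly drawn reduced model with closed-form reference values."""

    kind: str
    seed: int
    chemical: VOCParameterSet | None
    physiology: PhysiologySpec | None
    scenario: ExposureScenario | None
    pool_rate_per_h: float | None
    initial_amount_mg: float | None
    analytic: Mapping[str, float] = field(default_factory=dict)


def generate_synthetic_fixture(kind: str, seed: int) -> SyntheticFixture:
    """Deterministically draw a test fixture whose reduced model has a
    closed-form solution.

    * ``voc-like``: a metabolism-free volatile under constant inhalation;
      the analytic venous steady state is P_b * C_inh.
    * ``linear-metal``: a single first-order pool; the analytic amount at
      24 h is A0 * exp(-24 k), and its constant-infusion steady state is
      rate / k.
    """
    rng = np.random.default_rng(seed)
    if kind == "voc-like":
        partitions = {t: float(rng.uniform(0.5, 3.0)) for t in voc.TISSUES}
        p_b = float(rng.uniform(2.0, 15.0))
        mw = float(rng.uniform(50.0, 200.0))
        ppm = float(rng.uniform(0.1, 10.0))
        chem = VOCParameterSet(chemical=f"SYN{seed}", molecular_weight=mw,
                               blood_air_partition=p_b,
                               tissue_blood_partitions=partitions,
                               vmax_c=0.0, km=1.0, synthetic=True)
        phys = voc.load_default_physiology()
        duration = 400.0
        scenario = ExposureScenario(duration_h=duration,
                                    inhalation_ppm=[(0.0, duration, ppm)],
                                    oral_mg_per_kg_day=0.0,
                                    scenario_id=f"fixture:voc-like:{seed}")
        c_inh = units.ppm_to_mg_per_L(ppm, mw)
        return SyntheticFixture(kind=kind, seed=seed, chemical=chem, physiology=phys,
                                scenario=scenario, pool_rate_per_h=None,
                                initial_amount_mg=None,
                                analytic={"c_inh_mg_per_L": c_inh,
                                          "c_ven_ss_mg_per_L": p_b * c_inh})
    if kind == "linear-metal":
        k = float(rng.uniform(0.05, 0.5))
        a0 = float(rng.uniform(1.0, 100.0))
        return SyntheticFixture(kind=kind, seed=seed, chemical=None, physiology=None,
                                scenario=None, pool_rate_per_h=k, initial_amount_mg=a0,
                                analytic={"amount_24h_mg": a0 * float(np.exp(-24.0 * k)),
                                          "half_life_h": float(np.log(2) / k)})
    raise ScenarioError(f"unknown fixture kind {kind!r}")


# -- report bundle ---------------------------------------------------------

_CONFIG_KEYS = {"chemicals", "mrl", "scenario", "physiology", "out_dir", "solver"}


def validate_report_config(config: Mapping) -> list[str]:
    """Collect every problem with a report configuration (no first-failure)."""
    problems = []
    unknown = set(config) - _CONFIG_KEYS
    for k in sorted(unknown):
        problems.append(f"unknown configuration key {k!r}")
    chems = config.get("chemicals", list(voc.BUNDLED_CHEMICALS))
    if not isinstance(chems, (list, tuple)) or not chems:
        problems.append("'chemicals' must be a non-empty list")
    else:
        for c in chems:
            cc = str(c).upper().replace("CL4", "Cl4")
            if cc not in voc.BUNDLED_CHEMICALS:
                problems.append(f"unknown chemical {c!r}; bundled: {list(voc.BUNDLED_CHEMICALS)}")
    solver = config.get("solver", {})
    if not isinstance(solver, Mapping):
        problems.append("'solver' must be a mapping")
    else:
        for key in ("rtol", "atol"):
            if key in solver and (not isinstance(solver[key], (int, float)) or solver[key] <= 0):
                problems.append(f"solver.{key} must be a positive number")
    return problems


def run_report(config: Mapping | str | Path, out_dir: str | Path) -> dict:
    """Run the MRL screen described by ``config`` and write a report bundle.

    Writes per-chemical long-format time series CSVs, a summary JSON, a
    verdict CSV and a log of parameter provenance and fallbacks.  Fully
    deterministic given the configuration.
    """
    if not isinstance(config, Mapping):
        config = json.loads(Path(config).read_text())
    problems = validate_report_config(config)
    if problems:
        raise ConfigError(problems)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    solver_cfg = config.get("solver", {})
    settings = SolverSettings(**{k: solver_cfg[k] for k in ("rtol", "atol") if k in solver_cfg})
    phys = voc.load_default_physiology()
    chems = [str(c) for c in config.get("chemicals", list(voc.BUNDLED_CHEMICALS))]

    log_lines = [f"physiology: default adult, BW={phys.body_weight_kg} kg"]
    entries = [e for e in load_mrl_table()
               if e.chemical in {c.upper().replace("CL4", "Cl4") for c in chems}]
    summaries = {}
    rows = []
    for entry in entries:
        chem = voc.load_voc_parameters(entry.chemical)
        log_lines.append(f"{entry.chemical}: citation: {chem.citation}")
        for tissue, why in chem.substituted_partitions.items():
            log_lines.append(f"{entry.chemical}: substitution: {tissue}: {why}")
        scenario = build_mrl_scenario(entry)
        result = voc.simulate_voc(chem, phys, scenario, settings)
        frame = result.to_frame()
        csv_path = out / f"timeseries_{entry.chemical}.csv"
        frame.to_csv(csv_path, index=False, float_format="%.10g")
        s = voc.peak_and_window_summary(result)
        s["duration_class"] = entry.duration_class
        s["mass_balance_residual"] = engine.mass_balance_residual(result)
        summaries[entry.chemical] = s
        rows.append(entry)
        log_lines.append(f"{entry.chemical}: wrote {csv_path.name}")

    predictions = {c: s["peak_ng_per_mL"] for c, s in summaries.items()}
    verdicts = screen_against_biomonitoring(predictions, load_biomonitoring_table())
    pd.DataFrame([dataclasses.asdict(v) for v in verdicts]).to_csv(
        out / "verdicts.csv", index=False)
    (out / "summary.json").write_text(json.dumps(summaries, indent=1, default=str))
    (out / "report.log").write_text("\n".join(log_lines) + "\n")
    return {"summaries": summaries, "verdicts": verdicts, "out_dir": str(out)}
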