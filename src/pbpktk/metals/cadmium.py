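"""Age- and sex-dependent cadmium toxicokinetics.

Daily-step difference-equation model in the Nordberg-Kjellstrom lineage
(as modified by Choudhury 2001 / Diamond 2003): gut uptake into a fast
plasma pool, exchange with red cells and a metallothionein-bound blood
pool, slow accumulation in liver, kidney and remaining tissue, and urinary
and fecal excretion.  Hepatic Cd released as Cd-metallothionein is routed
preferentially to the kidney, which dominates the urinary signal.  Growth
curves supply body and organ weights versus age so burdens (ug) become
age-specific concentrations (ug/g), and urinary output is normalized per
gram of creatinine excreted.

All coefficients live in ``data/metals/cadmium.json`` with a citation and
are replaceable; nothing numeric is hard-coded here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np

from ..errors import DataError, ParameterError

POOLS = ("plasma", "rbc", "blood_mt", "liver", "kidney", "other")
SINKS = ("urine", "feces")


def _interp_table(table: Mapping, xkey: str, ykey: str) -> Callable[[float], float]:
    x = np.asarray(table[xkey], dtype=float)
    y = np.asarray(table[ykey], dtype=float)
    return lambda a: float(np.interp(a, x, y))


@dataclass(frozen=True)
class CadmiumParameters:
    """Transfer coefficients, growth algorithm and creatinine excretion."""

    absorption_fraction: Mapping[str, float]
    transfers_per_day: Mapping[str, Mapping[str, float]]
    growth: Mapping[str, Mapping]
    organ_weight_fractions: Mapping[str, Mapping]
    creatinine_mg_per_kg_day: Mapping[str, Mapping]
    max_age_years: float = 90.0
    citation: str | None = None

    def __post_init__(self):
        for sex, f in self.absorption_fraction.items():
            if not 0 <= f <= 1:
                raise ParameterError(f"absorption fraction for {sex} outside [0, 1]")
        for src, targets in self.transfers_per_day.items():
            if src not in POOLS:
                raise ParameterError(f"transfer from unknown pool {src!r}")
            total = 0.0
            for tgt, frac in targets.items():
                if tgt not in POOLS and tgt not in SINKS:
                    raise ParameterError(f"transfer {src}->{tgt}: unknown target")
                if frac < 0:
                    raise ParameterError(f"transfer {src}->{tgt}: negative fraction")
                total += frac
            if total > 1 + 1e-12:
                raise ParameterError(f"outgoing fractions from {src!r} sum to {total} > 1")

    # age-dependent anatomy -------------------------------------------------
    def body_weight_kg(self, age_years: float, sex: str) -> float:
        g = self.growth[sex]
        return float(np.interp(age_years, g["ages"], g["bw_kg"]))

    def organ_weight_g(self, organ: str, age_years: float, sex: str) -> float:
        t = self.organ_weight_fractions[organ]
        frac = float(np.interp(age_years, t["ages"], t["fraction"]))
        return frac * self.body_weight_kg(age_years, sex) * 1000.0

    def creatinine_g_per_day(self, age_years: float, sex: str) -> float:
        try:
            t = self.creatinine_mg_per_kg_day[sex]
        except KeyError:
            raise DataError(f"no creatinine data for sex {sex!r}") from None
        per_kg = float(np.interp(age_years, t["ages"], t["value"]))
        value = per_kg * self.body_weight_kg(age_years, sex) / 1000.0
        if value <= 0:
            raise DataError(f"creatinine excretion non-positive at age {age_years}")
        return value


def load_cadmium_parameters() -> CadmiumParameters:
    raw = json.loads(resources.files("pbpktk.data").joinpath("metals/cadmium.json").read_text())
    return CadmiumParameters(
        absorption_fraction=raw["absorption_fraction"],
        transfers_per_day=raw["transfers_per_day"],
        growth=raw["growth"],
        organ_weight_fractions=raw["organ_weight_fractions"],
        creatinine_mg_per_kg_day=raw["creatinine_mg_per_kg_day"],
        max_age_years=raw.get("max_age_years", 90.0),
        citation=raw.get("citation"),
    )


def load_nhanes_intake(sex: str) -> Callable[[float], float]:
    """Stepwise GM dietary intake (ug/day) versus age for one sex."""
    raw = json.loads(resources.files("pbpktk.data").joinpath("metals/cd_intake_nhanes.json").read_text())
    groups = raw[sex]["age_groups"]
    values = raw[sex]["intake_ug_per_day"]

    def intake(age_years: float) -> float:
        if age_years < groups[0][0]:
            return values[0]
        for (lo, hi), v in zip(groups, values):
            if lo <= age_years <= hi:
                return v
        return values[-1]

    return intake


@dataclass
class CadmiumResult:
    """Daily trajectories of burdens, excretion and derived concentrations."""

    sex: str
    age_years: np.ndarray           # daily grid
    burdens_ug: dict[str, np.ndarray]
    cumulative_urine_ug: np.ndarray
    cumulative_feces_ug: np.ndarray
    cumulative_intake_ug: np.ndarray
    urinary_rate_ug_per_day: np.ndarray
    urinary_ug_per_g_creatinine: np.ndarray
    kidney_conc_ug_per_g: np.ndarray
    liver_conc_ug_per_g: np.ndarray
    metadata: dict = field(default_factory=dict)

    def at_age(self, age_years: float, series: str) -> float:
        arr = getattr(self, series, None)
        if arr is None:
            arr = self.burdens_ug[series]
        return float(np.interp(age_years, self.age_years, arr))


def simulate_cadmium(sex: str,
                     intake_ug_per_day: Callable[[float], float] | float,
                     max_age_years: float = 90.0,
                     parameters: CadmiumParameters | None = None,
                     smoking_absorbed_ug_per_day: Callable[[float], float] | float = 0.0,
                     ) -> CadmiumResult:
    """Run the daily difference-equation model from birth to ``max_age_years``.

    ``intake_ug_per_day`` is dietary intake versus age (constant or a
    function of age in years); the optional smoking channel adds directly
    absorbed inhalation intake (ug/day, default off, matching nonsmoker
    biomonitoring comparisons).
    """
    if sex not in ("male", "female"):
        raise ParameterError(f"sex must be 'male' or 'female', got {sex!r}")
    p = parameters or load_cadmium_parameters()
    if max_age_years <= 0 or max_age_years > p.max_age_years:
        raise ParameterError(
            f"max age {max_age_years} outside the growth algorithm domain (0, {p.max_age_years}]")
    diet = intake_ug_per_day if callable(intake_ug_per_day) else (lambda a, _v=float(intake_ug_per_day): _v)
    smoke = (smoking_absorbed_ug_per_day if callable(smoking_absorbed_ug_per_day)
             else (lambda a, _v=float(smoking_absorbed_ug_per_day): _v))
    f_abs = p.absorption_fraction[sex]

    n_days = int(round(max_age_years * 365.0))
    ages = np.arange(n_days + 1) / 365.0
    A = {pool: np.zeros(n_days + 1) for pool in POOLS}
    urine = np.zeros(n_days + 1)
    feces = np.zeros(n_days + 1)
    intake_cum = np.zeros(n_days + 1)
    urine_rate = np.zeros(n_days + 1)

    # flatten transfer map once
    moves = [(src, tgt, frac)
             for src, targets in p.transfers_per_day.items()
             for tgt, frac in targets.items()]

    state = {pool: 0.0 for pool in POOLS}
    cum_u = cum_f = cum_i = 0.0
    for d in range(1, n_days + 1):
        age = ages[d - 1]
        diet_today = max(diet(age), 0.0)
        smoke_today = max(smoke(age), 0.0)
        fluxes = {(src, tgt): state[src] * frac for src, tgt, frac in moves}
        day_urine = 0.0
        for (src, tgt), amt in fluxes.items():
            state[src] -= amt
            if tgt == "urine":
                cum_u += amt
                day_urine += amt
            elif tgt == "feces":
                cum_f += amt
            else:
                state[tgt] += amt
        absorbed = f_abs * diet_today + smoke_today
        state["plasma"] += absorbed
        cum_f += (1.0 - f_abs) * diet_today
        cum_i += diet_today + smoke_today
        for pool in POOLS:
            A[pool][d] = state[pool]
        urine[d], feces[d], intake_cum[d] = cum_u, cum_f, cum_i
        urine_rate[d] = day_urine

    kidney_w = np.array([p.organ_weight_g("kidney", a, sex) for a in ages])
    liver_w = np.array([p.organ_weight_g("liver", a, sex) for a in ages])
    creat = np.array([p.creatinine_g_per_day(a, sex) if a > 0 else np.nan for a in ages])
    with np.errstate(invalid="ignore"):
        urinary_norm = urine_rate / creat
    urinary_norm[0] = 0.0

    return CadmiumResult(
        sex=sex,
        age_years=ages,
        burdens_ug={k: v for k, v in A.items()},
        cumulative_urine_ug=urine,
        cumulative_feces_ug=feces,
        cumulative_intake_ug=intake_cum,
        urinary_rate_ug_per_day=urine_rate,
        urinary_ug_per_g_creatinine=urinary_norm,
        kidney_conc_ug_per_g=A["kidney"] / kidney_w,
        liver_conc_ug_per_g=A["liver"] / liver_w,
        metadata={"citation": p.citation, "absorption_fraction": f_abs},
    )


def mass_balance_residual(result: CadmiumResult, eps: float = 1e-12) -> float:
    """|cumulative intake - (burdens + urine + feces)| / max(intake, eps)."""
    burden = sum(result.burdens_ug.values())
    gap = np.abs(result.cumulative_intake_ug - burden
                 - result.cumulative_urine_ug - result.cumulative_feces_ug)
    return float(np.max(gap) / max(float(result.cumulative_intake_ug[-1]), eps))


def creatinine_normalize(urinary_ug_per_day: float, age_years: float, sex: str,
                         parameters: CadmiumParameters | None = None) -> float:
    """Express a urinary excretion rate as ug per g creatinine."""
    p = parameters or load_cadmium_parameters()
    return urinary_ug_per_day / p.creatinine_g_per_day(age_years, sex)


def creatinine_denormalize(urinary_ug_per_g: float, age_years: float, sex: str,
                           parameters: CadmiumParameters | None = None) -> float:
    p = parameters or load_cadmium_parameters()
    return urinary_ug_per_g * p.creatinine_g_per_day(age_years, sex)


def predict_nhanes_profile(sex: str, parameters: CadmiumParameters | None = None):
    """Predicted urinary Cd (ug/g creatinine) at each NHANES age stratum.

    Runs a lifetime simulation under the stratified GM dietary intakes and
    reads the prediction at each stratum midpoint.  Returns a list of
    (age_lo, age_hi, predicted) tuples.
    """
    raw = json.loads(resources.files("pbpktk.data").joinpath("metals/cd_intake_nhanes.json").read_text())
    groups = raw[sex]["age_groups"]
    result = simulate_cadmium(sex, load_nhanes_intake(sex), parameters=parameters)
    out = []
    for lo, hi in groups:
        mid = 0.5 * (lo + min(hi, 80))
        out.append((lo, hi, result.at_age(mid, "urinary_ug_per_g_creatinine")))
    return out
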