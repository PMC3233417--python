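"""Multi-species arsenic PBPK model.

Four interconnected flow-limited sub-models -- inorganic As(V), As(III),
and the methylated metabolites MMA and DMA -- each with lung, liver, GI
tract, kidney, muscle, brain, skin and heart compartments plus a venous
blood pool.  As(V) and As(III) interconvert by first-order reduction and
oxidation in liver and kidney; methylation As(III) -> MMA -> DMA is a
saturable (Michaelis-Menten) hepatic step; each species is cleared to
urine from the kidney.  Oral doses enter a gut pool as the administered
species (arsenate -> As(V), arsenite -> As(III)) and are absorbed into the
liver, so the entry species shapes the urinary speciation.

Everything is tracked in ug of arsenic equivalents, so interconversion
conserves elemental mass exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

from ..engine import SolverSettings, integrate_states
from ..errors import ParameterError

SPECIES = ("AsV", "AsIII", "MMA", "DMA")
FORMS = {"arsenate": "AsV", "arsenite": "AsIII"}


@dataclass(frozen=True)
class ArsenicParameters:
    tissues: tuple[str, ...]
    body_weight_kg: float
    cardiac_output_L_per_h: float
    blood_volume_L: float
    volumes_L: Mapping[str, float]
    flows_L_per_h: Mapping[str, float]
    partitions: Mapping[str, Mapping[str, float]]
    reduction_per_h: Mapping[str, float]
    oxidation_per_h: Mapping[str, float]
    methylation: Mapping[str, Mapping[str, float]]
    urinary_clearance_L_per_h: Mapping[str, float]
    oral_ka_per_h: float
    gut_to_feces_per_h: float
    citation: str | None = None

    def __post_init__(self):
        for s in SPECIES:
            for t in self.tissues:
                if not (self.partitions[s][t] > 0):
                    raise ParameterError(f"partition for {s}/{t} must be positive")
        for rates in (self.reduction_per_h, self.oxidation_per_h, self.urinary_clearance_L_per_h):
            for k, v in rates.items():
                if v < 0:
                    raise ParameterError(f"negative rate for {k!r}")


def load_arsenic_parameters() -> ArsenicParameters:
    raw = json.loads(resources.files("pbpktk.data").joinpath("metals/arsenic.json").read_text())
    bw = raw["body_weight_kg"]
    qc = raw["cardiac_output_L_per_h"]
    vols = {t: raw["volume_fractions"][t] * bw for t in raw["tissues"]}
    flows = {t: raw["flow_fractions"][t] * qc for t in raw["tissues"]}
    return ArsenicParameters(
        tissues=tuple(raw["tissues"]),
        body_weight_kg=bw,
        cardiac_output_L_per_h=qc,
        blood_volume_L=raw["blood_volume_fraction"] * bw,
        volumes_L=vols,
        flows_L_per_h=flows,
        partitions=raw["partitions"],
        reduction_per_h=raw["reduction_per_h"],
        oxidation_per_h=raw["oxidation_per_h"],
        methylation=raw["methylation"],
        urinary_clearance_L_per_h=raw["urinary_clearance_L_per_h"],
        oral_ka_per_h=raw["oral_ka_per_h"],
        gut_to_feces_per_h=raw["gut_to_feces_per_h"],
        citation=raw.get("citation"),
    )


class ArsenicRHS:
    """Derivative function over the stacked four-species state vector.

    Layout: for each species, [venous blood, tissues...]; then the gut
    pool, per-species urine ledgers, and the feces ledger.
    """

    def __init__(self, p: ArsenicParameters, entry_species: str):
        self.p = p
        self.entry = entry_species
        nt = len(p.tissues)
        self.block = nt + 1  # blood + tissues per species
        self.names: list[str] = []
        for s in SPECIES:
            self.names.append(f"{s}:blood")
            self.names += [f"{s}:{t}" for t in p.tissues]
        self.i_gut = len(self.names)
        self.names.append("gut")
        self.i_urine = {}
        for s in SPECIES:
            self.i_urine[s] = len(self.names)
            self.names.append(f"urine:{s}")
        self.i_feces = len(self.names)
        self.names.append("feces")
        self.index = {n: i for i, n in enumerate(self.names)}

        self._V = np.array([p.volumes_L[t] for t in p.tissues])
        self._Q = np.array([p.flows_L_per_h[t] for t in p.tissues])
        self._P = {s: np.array([p.partitions[s][t] for t in p.tissues]) for s in SPECIES}
        self._ti = {t: k for k, t in enumerate(p.tissues)}

    def n_states(self) -> int:
        return len(self.names)

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        p = self.p
        dy = np.zeros_like(y)
        qc = p.cardiac_output_L_per_h
        cv_liver = {}
        for k, s in enumerate(SPECIES):
            o = k * self.block
            a_blood = y[o]
            a_tis = y[o + 1: o + self.block]
            c_ven = a_blood / p.blood_volume_L
            c_out = (a_tis / self._V) / self._P[s]
            dy[o + 1: o + self.block] += self._Q * (c_ven - c_out)
            dy[o] += float(np.dot(self._Q, c_out)) - qc * c_ven
            cv_liver[s] = c_out[self._ti["liver"]]
            # renal clearance to urine
            cl = p.urinary_clearance_L_per_h[s]
            rate_u = cl * c_out[self._ti["kidney"]]
            dy[o + 1 + self._ti["kidney"]] -= rate_u
            dy[self.i_urine[s]] += rate_u

        # redox interconversion As(V) <-> As(III) in liver and kidney
        oV, oIII = 0, self.block
        for organ, k_red in p.reduction_per_h.items():
            i = 1 + self._ti[organ]
            flux = k_red * y[oV + i]
            dy[oV + i] -= flux
            dy[oIII + i] += flux
        for organ, k_ox in p.oxidation_per_h.items():
            i = 1 + self._ti[organ]
            flux = k_ox * y[oIII + i]
            dy[oIII + i] -= flux
            dy[oV + i] += flux

        # hepatic methylation chain (saturable)
        il = 1 + self._ti["liver"]
        m1 = p.methylation["AsIII_to_MMA"]
        cv = max(cv_liver["AsIII"], 0.0)
        r1 = m1["vmax_ug_per_h"] * cv / (m1["km_ug_per_L"] + cv)
        dy[oIII + il] -= r1
        dy[2 * self.block + il] += r1
        m2 = p.methylation["MMA_to_DMA"]
        cv = max(cv_liver["MMA"], 0.0)
        r2 = m2["vmax_ug_per_h"] * cv / (m2["km_ug_per_L"] + cv)
        dy[2 * self.block + il] -= r2
        dy[3 * self.block + il] += r2

        # gut: absorption into liver of entry species + fecal loss
        a_gut = y[self.i_gut]
        k_ent = SPECIES.index(self.entry)
        dy[self.i_gut] -= (p.oral_ka_per_h + p.gut_to_feces_per_h) * a_gut
        dy[k_ent * self.block + il] += p.oral_ka_per_h * a_gut
        dy[self.i_feces] += p.gut_to_feces_per_h * a_gut
        return dy


@dataclass
class ArsenicResult:
    time_h: np.ndarray
    states: np.ndarray
    rhs: ArsenicRHS
    dose_ug: float
    form: str
    metadata: dict = field(default_factory=dict)

    def series(self, name: str) -> np.ndarray:
        return self.states[:, self.rhs.index[name]]

    def cumulative_urine(self, species: str) -> np.ndarray:
        return self.series(f"urine:{species}")

    def cumulative_urine_inorganic(self) -> np.ndarray:
        return self.cumulative_urine("AsV") + self.cumulative_urine("AsIII")

    def total_in_system(self) -> np.ndarray:
        return self.states.sum(axis=1)

    def mass_balance_residual(self, eps: float = 1e-12) -> float:
        gap = np.abs(self.total_in_system() - self.dose_ug)
        return float(np.max(gap) / max(self.dose_ug, eps))


def simulate_arsenic(dose_ug: float, form: str, duration_h: float = 168.0,
                     parameters: ArsenicParameters | None = None,
                     settings: SolverSettings | None = None) -> ArsenicResult:
    """Single oral dose of arsenate or arsenite, followed for ``duration_h``."""
    if dose_ug < 0:
        raise ParameterError("dose must be non-negative")
    if form not in FORMS:
        raise ParameterError(f"unknown arsenic form {form!r}; expected one of {sorted(FORMS)}")
    p = parameters or load_arsenic_parameters()
    rhs = ArsenicRHS(p, FORMS[form])
    y0 = np.zeros(rhs.n_states())
    y0[rhs.i_gut] = dose_ug
    settings = settings or SolverSettings(output_dt_h=0.25)
    times, states = integrate_states(rhs, y0, duration_h, settings, event_index=rhs.index)
    states = np.clip(states, 0.0, None)
    return ArsenicResult(time_h=times, states=states, rhs=rhs, dose_ug=dose_ug,
                         form=form, metadata={"citation": p.citation})
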