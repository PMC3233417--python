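"""Methylmercury compartmental toxicokinetics.

Pure linear first-order transfer system patterned after the Carrier-type
human model: blood exchanging with liver, kidney and brain; irreversible
sinks for hair, urine and feces.  Dietary intake is absorbed into blood
with a fixed GI absorption fraction, the unabsorbed remainder passing
directly to feces.  Hair is modeled as an irreversible sink whose running
concentration is the capture flux divided by the daily hair-growth mass.

Units: ug and days.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping

import numpy as np

from ..engine import SolverSettings, integrate_states
from ..errors import ParameterError

POOLS = ("blood", "liver", "kidney", "brain")
SINKS = ("hair", "urine", "feces")


@dataclass(frozen=True)
class MeHgParameters:
    absorption_fraction: float
    rates_per_day: Mapping[str, Mapping[str, float]]
    hair_growth_g_per_day: float
    citation: str | None = None

    def __post_init__(self):
        if not 0 <= self.absorption_fraction <= 1:
            raise ParameterError("absorption fraction must be in [0, 1]")
        if self.hair_growth_g_per_day <= 0:
            raise ParameterError("hair growth mass must be positive")
        for src, targets in self.rates_per_day.items():
            if src not in POOLS:
                raise ParameterError(f"rate from unknown pool {src!r}")
            for tgt, k in targets.items():
                if tgt not in POOLS and tgt not in SINKS:
                    raise ParameterError(f"rate {src}->{tgt}: unknown target")
                if k < 0:
                    raise ParameterError(f"rate {src}->{tgt}: negative")


def load_mehg_parameters() -> MeHgParameters:
    raw = json.loads(resources.files("pbpktk.data").joinpath("metals/mehg.json").read_text())
    return MeHgParameters(
        absorption_fraction=raw["absorption_fraction"],
        rates_per_day=raw["rates_per_day"],
        hair_growth_g_per_day=raw["hair_growth_g_per_day"],
        citation=raw.get("citation"),
    )


STATES = POOLS + SINKS + ("intake",)


def _rate_matrix(p: MeHgParameters) -> np.ndarray:
    idx = {n: i for i, n in enumerate(STATES)}
    n = len(STATES)
    M = np.zeros((n, n))
    for src, targets in p.rates_per_day.items():
        for tgt, k in targets.items():
            M[idx[src], idx[src]] -= k
            M[idx[tgt], idx[src]] += k
    return M


@dataclass
class MeHgResult:
    time_days: np.ndarray
    states: np.ndarray
    hair_conc_ug_per_g: np.ndarray
    metadata: dict = field(default_factory=dict)

    def series(self, name: str) -> np.ndarray:
        return self.states[:, STATES.index(name)]

    def mass_balance_residual(self, eps: float = 1e-12) -> float:
        body_and_excreta = self.states[:, : len(POOLS) + len(SINKS)].sum(axis=1)
        intake = self.series("intake")
        gap = np.abs(intake - body_and_excreta)
        return float(np.max(gap) / max(float(intake[-1]), eps))


def simulate_mehg(intake_ug_per_day: Callable[[float], float] | float,
                  duration_days: float,
                  parameters: MeHgParameters | None = None,
                  settings: SolverSettings | None = None) -> MeHgResult:
    """Integrate the linear system under a dietary intake schedule (ug/day)."""
    if duration_days <= 0:
        raise ParameterError("duration must be positive")
    p = parameters or load_mehg_parameters()
    intake = (intake_ug_per_day if callable(intake_ug_per_day)
              else (lambda t, _v=float(intake_ug_per_day): _v))
    M = _rate_matrix(p)
    i_blood = STATES.index("blood")
    i_feces = STATES.index("feces")
    i_intake = STATES.index("intake")
    f = p.absorption_fraction

    def rhs(t, y):
        dy = M @ y
        r = max(intake(t), 0.0)
        dy[i_blood] += f * r
        dy[i_feces] += (1.0 - f) * r
        dy[i_intake] += r
        return dy

    settings = settings or SolverSettings(output_dt_h=0.25)  # grid spacing in days here
    index = {n: i for i, n in enumerate(STATES)}
    times, states = integrate_states(rhs, np.zeros(len(STATES)), duration_days,
                                     settings, event_index=index)
    states = np.clip(states, 0.0, None)

    k_hair = p.rates_per_day.get("blood", {}).get("hair", 0.0)
    hair_conc = k_hair * states[:, i_blood] / p.hair_growth_g_per_day
    return MeHgResult(time_days=times, states=states, hair_conc_ug_per_g=hair_conc,
                      metadata={"citation": p.citation})
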