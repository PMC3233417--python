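"""Generic well-mixed, flow-limited compartmental machinery.

All tissue compartments follow the perfusion-limited mass balance

    dA_i/dt = Q_i * (C_art - C_i / P_i)

where ``A_i`` is the amount (mg) in tissue i, ``Q_i`` its blood flow (L/h),
``C_i = A_i / V_i`` its concentration (mg/L), ``P_i`` its tissue:blood
partition coefficient and ``C_art`` the arterial blood concentration.  A
venous blood pool collects tissue outflow; if a gas-exchange step is
present, arterial blood leaves the lung at the algebraic steady state

    C_art = (Qc * C_ven + Qp * C_inh) / (Qc + Qp / P_b)

with alveolar (exhaled) air at ``C_art / P_b``.

On top of the perfused circuit, a structure may declare extra well-mixed
*pools* (e.g. a gut lumen), first-order *transfers* between states or into
excretion ledgers, time/state-dependent *sources* (e.g. dermal flux), and a
single saturable metabolism sink.  Every mg entering the system is recorded
in an intake ledger and every mg leaving in a loss ledger, so conservation
can be audited after the fact with :func:`mass_balance_residual`.

Units: hours, mg, litres throughout (tissue density 1 kg/L, so volume
fractions of body weight are litres).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ParameterError, SolverError, StructureError

__all__ = [
    "PhysiologySpec",
    "SolverSettings",
    "TissueSpec",
    "GasExchangeSpec",
    "Transfer",
    "Source",
    "MetabolismSpec",
    "FlowLimitedStructure",
    "BolusEvent",
    "RHS",
    "SimulationResult",
    "arterial_concentration",
    "assemble_rhs",
    "integrate",
    "integrate_states",
    "mass_balance_residual",
]

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class PhysiologySpec:
    """Body size, circulation and tissue composition of one individual.

    Volumes are unitless fractions of body weight (density 1 kg/L, so a
    fraction times BW in kg is litres); flows are fractions of cardiac
    output.  Flow fractions over the perfused compartments must sum to 1.
    """

    body_weight_kg: float
    cardiac_output_L_per_h: float
    alveolar_ventilation_L_per_h: float
    volume_fractions: Mapping[str, float]
    flow_fractions: Mapping[str, float]

    def __post_init__(self):
        if self.body_weight_kg <= 0:
            raise ParameterError("body weight must be positive")
        if self.cardiac_output_L_per_h <= 0 or self.alveolar_ventilation_L_per_h < 0:
            raise ParameterError("cardiac output must be positive, ventilation non-negative")
        for label, d in (("volume", self.volume_fractions), ("flow", self.flow_fractions)):
            for name, v in d.items():
                if v < 0:
                    raise ParameterError(f"negative {label} fraction for {name!r}: {v}")
        vsum = sum(self.volume_fractions.values())
        if vsum > 1 + _FRACTION_TOL:
            raise ParameterError(f"volume fractions sum to {vsum:.6f} > 1")
        qsum = sum(self.flow_fractions.values())
        if abs(qsum - 1.0) > _FRACTION_TOL:
            raise ParameterError(f"flow fractions sum to {qsum!r}, expected 1")

    def volume_L(self, name: str) -> float:
        try:
            return self.volume_fractions[name] * self.body_weight_kg
        except KeyError:
            raise ParameterError(f"no volume fraction for compartment {name!r}") from None

    def flow_L_per_h(self, name: str) -> float:
        try:
            return self.flow_fractions[name] * self.cardiac_output_L_per_h
        except KeyError:
            raise ParameterError(f"no flow fraction for compartment {name!r}") from None


@dataclass(frozen=True)
class SolverSettings:
    """Integrator controls.

    Defaults (rtol 1e-8, atol 1e-10 mg, LSODA) are tight enough that the
    mass-balance residual of any bundled model stays below 1e-6.
    """

    rtol: float = 1e-8
    atol: float = 1e-10
    max_step_h: float = math.inf
    output_dt_h: float = 0.1
    method: str = "LSODA"

    def __post_init__(self):
        if self.rtol <= 0 or self.atol <= 0:
            raise ParameterError("solver tolerances must be positive")
        if self.output_dt_h <= 0 or self.max_step_h <= 0:
            raise ParameterError("step sizes must be positive")


@dataclass(frozen=True)
class TissueSpec:
    """One perfused, flow-limited tissue."""

    name: str
    volume_L: float
    flow_L_per_h: float
    partition: float  # tissue:blood

    def __post_init__(self):
        if self.volume_L <= 0:
            raise ParameterError(f"{self.name}: volume must be positive")
        if self.flow_L_per_h < 0:
            raise ParameterError(f"{self.name}: flow must be non-negative")
        if not (self.partition > 0):
            raise ParameterError(f"missing or non-positive partition coefficient for {self.name!r}")


@dataclass(frozen=True)
class GasExchangeSpec:
    alveolar_ventilation_L_per_h: float
    blood_air_partition: float
    inhaled_mg_per_L: Callable[[float], float]

    def __post_init__(self):
        if self.blood_air_partition <= 0:
            raise ParameterError("blood:air partition must be positive")
        if self.alveolar_ventilation_L_per_h < 0:
            raise ParameterError("ventilation must be non-negative")


@dataclass(frozen=True)
class Transfer:
    """First-order transfer ``rate_per_h * A_source`` between states.

    ``target`` may be another state or ``"ledger:<name>"`` for an
    irreversible excretion sink.
    """

    source: str
    target: str
    rate_per_h: float

    def __post_init__(self):
        if self.rate_per_h < 0:
            raise ParameterError(f"transfer {self.source}->{self.target}: negative rate")


@dataclass(frozen=True)
class Source:
    """Time/state dependent input ``rate(t, conc) -> mg/h`` into a state.

    ``conc`` maps compartment names to current concentrations (mg/L), so a
    source may depend on the receiving tissue (dermal flux does).  The same
    amount is accumulated in the named intake ledger.
    """

    target: str
    ledger: str
    rate: Callable[[float, Mapping[str, float]], float]


@dataclass(frozen=True)
class MetabolismSpec:
    """Saturable + first-order clearance from one tissue.

    rate = Vmax * Cv / (Km + Cv) + k1 * Cv * V, with Cv the venous-
    equilibrium concentration ``C_tissue / P_tissue``.
    """

    compartment: str
    vmax_mg_per_h: float
    km_mg_per_L: float
    first_order_per_h: float = 0.0

    def __post_init__(self):
        if self.vmax_mg_per_h < 0 or self.first_order_per_h < 0:
            raise ParameterError("metabolic rates must be non-negative")
        if self.vmax_mg_per_h > 0 and self.km_mg_per_L <= 0:
            raise ParameterError("Km must be positive when Vmax > 0")


@dataclass(frozen=True)
class FlowLimitedStructure:
    """Declarative model structure consumed by :func:`assemble_rhs`."""

    tissues: Sequence[TissueSpec] = ()
    blood_volume_L: float = 0.0
    cardiac_output_L_per_h: float = 0.0
    gas_exchange: GasExchangeSpec | None = None
    pools: Sequence[str] = ()
    transfers: Sequence[Transfer] = ()
    sources: Sequence[Source] = ()
    metabolism: MetabolismSpec | None = None
    extra_ledgers: Sequence[str] = ()
    name: str = "model"

    @property
    def has_circulation(self) -> bool:
        return len(self.tissues) > 0

    def with_inhalation(self, inhaled_mg_per_L: Callable[[float], float]) -> "FlowLimitedStructure":
        if self.gas_exchange is None:
            raise StructureError("structure has no gas-exchange compartment")
        return replace(self, gas_exchange=replace(self.gas_exchange, inhaled_mg_per_L=inhaled_mg_per_L))


@dataclass(frozen=True)
class BolusEvent:
    """Instantaneous dose: at ``time_h`` add ``amount_mg`` to ``target`` and
    to the intake ledger ``ledger``."""

    time_h: float
    target: str
    amount_mg: float
    ledger: str = "oral_intake"

    def __post_init__(self):
        if self.amount_mg < 0:
            raise ParameterError("bolus amount must be non-negative")


def arterial_concentration(c_ven: float, c_inh: float, qc: float, qp: float, p_b: float):
    """Steady-state gas-exchange (lung) equation.

    C_art = (Qc*C_ven + Qp*C_inh) / (Qc + Qp/P_b).  With Qp = 0 this
    degenerates to C_art = C_ven (no ventilation limit).
    """
    if qc <= 0:
        raise ParameterError("cardiac output must be positive")
    if qp < 0:
        raise ParameterError("ventilation must be non-negative")
    if p_b <= 0:
        raise ParameterError("blood:air partition must be positive")
    return (qc * c_ven + qp * c_inh) / (qc + qp / p_b)


class RHS:
    """Derivative function plus the state layout it was assembled for."""

    BLOOD = "venous_blood"

    def __init__(self, structure: FlowLimitedStructure):
        self.structure = structure
        names: list[str] = []
        if structure.has_circulation:
            if structure.blood_volume_L <= 0:
                raise StructureError("perfused structure requires a positive blood volume")
            if structure.cardiac_output_L_per_h <= 0:
                raise StructureError("perfused structure requires a positive cardiac output")
            qsum = sum(t.flow_L_per_h for t in structure.tissues)
            if abs(qsum - structure.cardiac_output_L_per_h) > 1e-6 * structure.cardiac_output_L_per_h:
                raise StructureError(
                    f"tissue flows sum to {qsum:.6g} L/h but cardiac output is "
                    f"{structure.cardiac_output_L_per_h:.6g} L/h; perfusion does not close")
            names.append(self.BLOOD)
        names += [t.name for t in structure.tissues]
        names += list(structure.pools)
        if len(set(names)) != len(names):
            raise StructureError(f"duplicate state names in {names}")
        self.body_states = tuple(names)

        ledgers: list[str] = []
        if structure.gas_exchange is not None:
            ledgers += ["inhaled_intake", "exhaled"]
        if structure.metabolism is not None:
            ledgers.append("metabolized")
        for tr in structure.transfers:
            if tr.target.startswith("ledger:"):
                led = tr.target.split(":", 1)[1]
                if led not in ledgers:
                    ledgers.append(led)
        for src in structure.sources:
            if src.ledger not in ledgers:
                ledgers.append(src.ledger)
        for led in structure.extra_ledgers:
            if led not in ledgers:
                ledgers.append(led)
        self.ledger_states = tuple(ledgers)
        self.names = self.body_states + self.ledger_states
        self.index = {n: i for i, n in enumerate(self.names)}

        # classify ledgers for the mass balance audit
        self.intake_ledgers = tuple(
            l for l in ledgers
            if l == "inhaled_intake" or any(s.ledger == l for s in structure.sources)
            or l.endswith("_intake"))
        self.loss_ledgers = tuple(l for l in ledgers if l not in self.intake_ledgers)

        # validate references
        known = set(self.names)
        for tr in structure.transfers:
            if tr.source not in self.body_states:
                raise StructureError(f"transfer from unknown state {tr.source!r}")
            if not tr.target.startswith("ledger:") and tr.target not in self.body_states:
                raise StructureError(f"transfer to unknown state {tr.target!r}")
        for src in structure.sources:
            if src.target not in self.body_states:
                raise StructureError(f"source targets unknown state {src.target!r}")
        met = structure.metabolism
        if met is not None:
            if met.compartment not in {t.name for t in structure.tissues} and met.compartment not in structure.pools:
                raise StructureError(f"metabolism attached to unknown compartment {met.compartment!r}")

        # precompute arrays for speed
        self._tissues = list(structure.tissues)
        self._n_tis = len(self._tissues)
        self._tis_idx = np.array([self.index[t.name] for t in self._tissues], dtype=int)
        self._tis_V = np.array([t.volume_L for t in self._tissues])
        self._tis_Q = np.array([t.flow_L_per_h for t in self._tissues])
        self._tis_P = np.array([t.partition for t in self._tissues])
        self._transfers = [(self.index[tr.source],
                            self.index[tr.target.split(":", 1)[1]] if tr.target.startswith("ledger:")
                            else self.index[tr.target],
                            tr.rate_per_h) for tr in structure.transfers]
        self._met = structure.metabolism
        if self._met is not None:
            self._met_i = self.index[self._met.compartment]
            tis_by_name = {t.name: t for t in self._tissues}
            if self._met.compartment in tis_by_name:
                t = tis_by_name[self._met.compartment]
                self._met_P, self._met_V = t.partition, t.volume_L
            else:
                self._met_P, self._met_V = 1.0, 1.0
        self._blood_i = self.index[self.BLOOD] if structure.has_circulation else None

    # -- helpers ----------------------------------------------------------
    def n_states(self) -> int:
        return len(self.names)

    def concentrations(self, y: np.ndarray) -> dict[str, float]:
        out: dict[str, float] = {}
        if self._blood_i is not None:
            out[self.BLOOD] = y[self._blood_i] / self.structure.blood_volume_L
        for t, i in zip(self._tissues, self._tis_idx):
            out[t.name] = y[i] / t.volume_L
        for p in self.structure.pools:
            out[p] = y[self.index[p]]  # pools are amounts, no defined volume
        return out

    def arterial(self, t: float, y: np.ndarray) -> float:
        ge = self.structure.gas_exchange
        c_ven = y[self._blood_i] / self.structure.blood_volume_L
        if ge is None:
            return c_ven
        return arterial_concentration(c_ven, ge.inhaled_mg_per_L(t),
                                      self.structure.cardiac_output_L_per_h,
                                      ge.alveolar_ventilation_L_per_h,
                                      ge.blood_air_partition)

    # -- the derivative ----------------------------------------------------
    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        s = self.structure
        dy = np.zeros_like(y)
        if self._blood_i is not None:
            qc = s.cardiac_output_L_per_h
            c_ven = y[self._blood_i] / s.blood_volume_L
            ge = s.gas_exchange
            if ge is not None:
                c_inh = ge.inhaled_mg_per_L(t)
                qp = ge.alveolar_ventilation_L_per_h
                c_art = (qc * c_ven + qp * c_inh) / (qc + qp / ge.blood_air_partition)
                dy[self.index["inhaled_intake"]] = qp * c_inh
                dy[self.index["exhaled"]] = qp * c_art / ge.blood_air_partition
            else:
                c_art = c_ven
            c_tis = y[self._tis_idx] / self._tis_V
            c_out = c_tis / self._tis_P  # venous-equilibrium concentration
            dy[self._tis_idx] = self._tis_Q * (c_art - c_out)
            dy[self._blood_i] = float(np.dot(self._tis_Q, c_out)) - qc * c_ven

        if self._met is not None:
            cv = max(y[self._met_i], 0.0) / self._met_V / self._met_P
            rate = self._met.first_order_per_h * cv * self._met_V
            if self._met.vmax_mg_per_h > 0:
                rate += self._met.vmax_mg_per_h * cv / (self._met.km_mg_per_L + cv)
            dy[self._met_i] -= rate
            dy[self.index["metabolized"]] += rate

        for i_src, i_dst, k in self._transfers:
            flux = k * y[i_src]
            dy[i_src] -= flux
            dy[i_dst] += flux

        if s.sources:
            conc = self.concentrations(y)
            for src in s.sources:
                r = src.rate(t, conc)
                dy[self.index[src.target]] += r
                dy[self.index[src.ledger]] += r
        return dy


def assemble_rhs(structure: FlowLimitedStructure) -> RHS:
    """Validate a structure and return its derivative function.

    Raises :class:`StructureError` for unknown compartment references or
    flows that do not close, :class:`ParameterError` for missing or
    non-positive partitions (raised eagerly by the component dataclasses).
    """
    return RHS(structure)


@dataclass
class SimulationResult:
    """Time grid plus per-compartment series and cumulative ledgers.

    ``concentrations`` are mg/L for blood and tissues; pool entries are
    amounts (mg).  ``amounts`` are mg for every body state.  ``ledger``
    holds cumulative intake/loss series (mg).
    """

    time_h: np.ndarray
    amounts: dict[str, np.ndarray]
    concentrations: dict[str, np.ndarray]
    ledger: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.time_h)
        for d in (self.amounts, self.concentrations, self.ledger):
            for k, v in d.items():
                if len(v) != n:
                    raise ValueError(f"series {k!r} length {len(v)} != grid length {n}")

    def series(self, name: str) -> np.ndarray:
        if name in self.concentrations:
            return self.concentrations[name]
        if name in self.ledger:
            return self.ledger[name]
        raise KeyError(name)

    def to_frame(self):
        """Long-format DataFrame: time_h, compartment, quantity, unit, value."""
        import pandas as pd

        rows = []
        for name, v in self.concentrations.items():
            unit = "mg" if name in self.metadata.get("pool_states", ()) else "mg/L"
            q = "amount" if unit == "mg" else "concentration"
            rows.append(pd.DataFrame({"time_h": self.time_h, "compartment": name,
                                      "quantity": q, "unit": unit, "value": v}))
        for name, v in self.ledger.items():
            rows.append(pd.DataFrame({"time_h": self.time_h, "compartment": name,
                                      "quantity": "cumulative", "unit": "mg", "value": v}))
        return pd.concat(rows, ignore_index=True)


def _segment_times(duration_h: float, events: Sequence[BolusEvent],
                   breakpoints: Sequence[float]) -> list[float]:
    cuts = {0.0, float(duration_h)}
    for ev in events:
        if not 0.0 <= ev.time_h <= duration_h:
            raise ParameterError(f"event at t={ev.time_h} h outside [0, {duration_h}]")
        cuts.add(float(ev.time_h))
    for b in breakpoints:
        if 0.0 < b < duration_h:
            cuts.add(float(b))
    return sorted(cuts)


def integrate_states(rhs: Callable, y0: np.ndarray, duration_h: float,
                     settings: SolverSettings,
                     events: Sequence[BolusEvent] = (),
                     breakpoints: Sequence[float] = (),
                     event_index: Mapping[str, int] | None = None,
                     grid: np.ndarray | None = None):
    """Low-level event-aware integration; returns (times, states matrix).

    Integration restarts exactly at every event/breakpoint time so no dose
    discontinuity straddles a solver step.  Bolus events add mass to the
    state given by ``event_index[target]`` (and its ledger, if indexed).
    """
    if grid is None:
        n = int(round(duration_h / settings.output_dt_h))
        grid = np.linspace(0.0, duration_h, n + 1)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ParameterError("output grid must be strictly increasing with >= 2 points")

    events = sorted(events, key=lambda e: e.time_h)
    cuts = _segment_times(duration_h, events, breakpoints)
    ev_at: dict[float, list[BolusEvent]] = {}
    for ev in events:
        ev_at.setdefault(float(ev.time_h), []).append(ev)

    y = np.array(y0, dtype=float)
    out = np.empty((len(grid), len(y)))
    filled = np.zeros(len(grid), dtype=bool)
    if grid[0] == 0.0:
        for ev in ev_at.get(0.0, ()):
            _apply_bolus(y, ev, event_index)
        out[0] = y
        filled[0] = True
    else:
        for ev in ev_at.get(0.0, ()):
            _apply_bolus(y, ev, event_index)

    for t0, t1 in zip(cuts[:-1], cuts[1:]):
        if t0 != 0.0:
            for ev in ev_at.get(t0, ()):
                _apply_bolus(y, ev, event_index)
        mask = (grid > t0) & (grid <= t1)
        t_eval = grid[mask]
        if len(t_eval) == 0 or t_eval[-1] < t1:
            t_eval = np.append(t_eval, t1)
        sol = solve_ivp(rhs, (t0, t1), y, method=settings.method,
                        rtol=settings.rtol, atol=settings.atol,
                        max_step=settings.max_step_h, t_eval=t_eval,
                        dense_output=False)
        if not sol.success:
            raise SolverError(f"integration failed in [{t0}, {t1}] h: {sol.message}", time_h=t0)
        k = int(mask.sum())
        if k:
            out[mask] = sol.y[:, :k].T
            filled[mask] = True
        y = sol.y[:, -1].copy()
        if np.min(y) < -1000.0 * settings.atol:
            raise SolverError(f"state went negative ({np.min(y):.3e} mg) at t={t1} h", time_h=t1)
        np.clip(y, 0.0, None, out=y)
    if not filled.all():
        raise SolverError("internal error: unfilled grid points")
    return grid, out


def _apply_bolus(y: np.ndarray, ev: BolusEvent, index: Mapping[str, int] | None):
    if index is None or ev.target not in index:
        raise ParameterError(f"bolus event targets unknown state {ev.target!r}")
    y[index[ev.target]] += ev.amount_mg
    if ev.ledger is not None:
        if ev.ledger not in index:
            raise ParameterError(
                f"bolus event books to undeclared ledger {ev.ledger!r}; add it to the "
                "structure's extra_ledgers")
        y[index[ev.ledger]] += ev.amount_mg


def integrate(rhs: RHS, initial_amounts: Mapping[str, float] | None,
              duration_h: float, settings: SolverSettings = SolverSettings(),
              events: Sequence[BolusEvent] = (),
              breakpoints: Sequence[float] = (),
              metadata: Mapping | None = None) -> SimulationResult:
    """Integrate an assembled structure and package a SimulationResult."""
    y0 = np.zeros(rhs.n_states())
    if initial_amounts:
        for name, amt in initial_amounts.items():
            if name not in rhs.index:
                raise ParameterError(f"initial amount for unknown state {name!r}")
            y0[rhs.index[name]] = amt
    times, states = integrate_states(rhs, y0, duration_h, settings,
                                     events=events, breakpoints=breakpoints,
                                     event_index=rhs.index, grid=None)
    states = np.clip(states, 0.0, None)

    amounts = {n: states[:, rhs.index[n]].copy() for n in rhs.body_states}
    ledger = {n: states[:, rhs.index[n]].copy() for n in rhs.ledger_states}
    conc: dict[str, np.ndarray] = {}
    s = rhs.structure
    if s.has_circulation:
        conc[RHS.BLOOD] = amounts[RHS.BLOOD] / s.blood_volume_L
    for t in s.tissues:
        conc[t.name] = amounts[t.name] / t.volume_L
    for p in s.pools:
        conc[p] = amounts[p]  # amount, flagged via metadata["pool_states"]

    meta = dict(metadata or {})
    meta.setdefault("solver_settings", settings)
    meta["body_states"] = rhs.body_states
    meta["pool_states"] = tuple(s.pools)
    meta["intake_ledgers"] = rhs.intake_ledgers
    meta["loss_ledgers"] = rhs.loss_ledgers
    meta["initial_burden_mg"] = float(sum(y0[rhs.index[n]] for n in rhs.body_states))

    if s.has_circulation and s.gas_exchange is not None:
        ge = s.gas_exchange
        qc, qp, pb = s.cardiac_output_L_per_h, ge.alveolar_ventilation_L_per_h, ge.blood_air_partition
        c_inh = np.array([ge.inhaled_mg_per_L(t) for t in times])
        c_art = (qc * conc[RHS.BLOOD] + qp * c_inh) / (qc + qp / pb)
        conc["arterial_blood"] = c_art
        conc["exhaled_air"] = c_art / pb
        meta["inhaled_air_series_mg_per_L"] = c_inh

    return SimulationResult(time_h=times, amounts=amounts, concentrations=conc,
                            ledger=ledger, metadata=meta)


def mass_balance_residual(result: SimulationResult, eps: float = 1e-12) -> float:
    """Max over time of |intake - (burden + losses)| / max(intake, eps).

    ``intake`` includes the initial burden plus every intake ledger;
    ``losses`` are the loss ledgers (exhaled, metabolized, excreted...).
    """
    if len(result.time_h) == 0:
        raise ValueError("empty simulation result")
    meta = result.metadata
    burden = np.zeros_like(result.time_h)
    for n in meta["body_states"]:
        burden = burden + result.amounts[n]
    intake = np.full_like(result.time_h, float(meta.get("initial_burden_mg", 0.0)))
    for l in meta["intake_ledgers"]:
        intake = intake + result.ledger[l]
    losses = np.zeros_like(result.time_h)
    for l in meta["loss_ledgers"]:
        losses = losses + result.ledger[l]
    gap = np.abs(intake - burden - losses)
    scale = max(float(np.max(intake)), eps)
    return float(np.max(gap) / scale)
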