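"""Model-evaluation statistics and the sensitivity-ratio robustness screen.

Comparisons between a simulated kinetic profile and an observed time-
concentration dataset are summarized by:

* AUC ratio ``AUC_r = AUC_model / AUC_data`` (trapezoidal rule on both;
  closer to 1 is better agreement);
* MSSD, the mean of squared simulated-minus-observed differences at the
  observation times (simulation linearly interpolated);
* performance errors ``PE_i = 100 * (pred_i - meas_i) / meas_i`` with
  MAPE% (median |PE|), MPE% (median PE), RMSPE% (sqrt(mean PE^2); a
  median-based variant is available), and the Pearson correlation r.

Robustness is probed with sensitivity ratios
``SR = (dY/Y) / (dX/X)`` under a small forward (optionally central)
perturbation of one input parameter; a positive SR means the output moves
with the input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import DataError, UnitError
from .engine import SimulationResult

__all__ = [
    "KineticDataset", "FitMetrics", "PerformanceErrors", "SensitivityEntry",
    "SensitivityReport", "auc_trapezoid", "auc_ratio", "mssd",
    "performance_errors", "fit_metrics", "sensitivity_ratio", "sensitivity_screen",
]


@dataclass(frozen=True)
class KineticDataset:
    """Observed concentration-time series with a mandatory unit tag."""

    times_h: Sequence[float]
    concentrations: Sequence[float]
    unit: str
    label: str = "blood"
    citation: str | None = None

    def __post_init__(self):
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or len(t) != len(c):
            raise DataError("times and concentrations must be 1-d and equally long")
        if len(t) >= 2 and np.any(np.diff(t) <= 0):
            raise DataError("observation times must be strictly increasing")
        if np.any(c < 0):
            raise DataError("observed concentrations must be non-negative")
        if not self.unit:
            raise DataError("a unit tag is required (e.g. 'mg/L', 'ppm', 'uM')")


def auc_trapezoid(times: Sequence[float], values: Sequence[float]) -> float:
    """Composite trapezoid area under a concentration-time curve."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 2:
        raise DataError("AUC needs at least two points")
    if np.any(np.diff(t) <= 0):
        raise DataError("times must be strictly increasing")
    return float(np.trapezoid(v, t))


def auc_ratio(auc_model: float, auc_data: float) -> float:
    """AUC_r = model AUC / data AUC; closer to one is better agreement."""
    if auc_data <= 0:
        raise DataError("data AUC must be positive")
    return auc_model / auc_data


def _predicted_at(simulation, data: KineticDataset, series: str,
                  sim_unit: str) -> np.ndarray:
    if data.unit.replace(" ", "") != sim_unit.replace(" ", ""):
        raise UnitError(
            f"dataset unit {data.unit!r} does not match simulation unit {sim_unit!r}; "
            "convert explicitly before comparing")
    if isinstance(simulation, SimulationResult):
        t_sim, c_sim = simulation.time_h, simulation.series(series)
    else:
        t_sim, c_sim = simulation  # (times, values) pair
        t_sim = np.asarray(t_sim, dtype=float)
        c_sim = np.asarray(c_sim, dtype=float)
    t_obs = np.asarray(data.times_h, dtype=float)
    if t_obs[0] < t_sim[0] or t_obs[-1] > t_sim[-1]:
        raise DataError("observation times fall outside the simulated span")
    return np.interp(t_obs, t_sim, c_sim)


def mssd(simulation, data: KineticDataset, series: str = "venous_blood",
         sim_unit: str = "mg/L") -> float:
    """Mean of squared simulated-minus-observed differences.

    The simulation is linearly interpolated to each observation time; the
    squared residuals are summed and divided by the number of data points.
    Units must match exactly (no silent conversion).
    """
    pred = _predicted_at(simulation, data, series, sim_unit)
    obs = np.asarray(data.concentrations, dtype=float)
    return float(np.mean((pred - obs) ** 2))


@dataclass(frozen=True)
class PerformanceErrors:
    pe_percent: np.ndarray
    mape_percent: float
    mpe_percent: float
    rmspe_percent: float
    r: float | None
    n: int
    r_note: str | None = None


def performance_errors(c_measured: Sequence[float], c_predicted: Sequence[float],
                       median_rmspe: bool = False,
                       log_scale_r: bool = False) -> PerformanceErrors:
    """Per-point percent performance errors and their summaries.

    PE_i = 100 (pred_i - meas_i)/meas_i; MAPE% = median |PE|; MPE% =
    median PE; RMSPE% = sqrt(sum PE^2 / n) (``median_rmspe=True`` swaps the
    mean for a median).  r is the Pearson correlation, flagged None when
    either series is constant.
    """
    meas = np.asarray(c_measured, dtype=float)
    pred = np.asarray(c_predicted, dtype=float)
    if meas.shape != pred.shape or meas.ndim != 1:
        raise DataError("measured and predicted series must be paired 1-d arrays")
    zero = np.nonzero(meas == 0)[0]
    if len(zero):
        raise DataError(f"measured concentration is zero at point index {int(zero[0])}; "
                        "PE is undefined there")
    pe = 100.0 * (pred - meas) / meas
    sq = np.median(pe ** 2) if median_rmspe else np.mean(pe ** 2)
    if log_scale_r:
        if np.any(meas <= 0) or np.any(pred <= 0):
            raise DataError("log-scale correlation needs strictly positive series")
        xm, xp = np.log(meas), np.log(pred)
    else:
        xm, xp = meas, pred
    r: float | None
    note = None
    if np.ptp(xm) == 0 or np.ptp(xp) == 0:
        r, note = None, "correlation undefined for a constant series"
    else:
        r = float(np.corrcoef(xm, xp)[0, 1])
    return PerformanceErrors(pe_percent=pe,
                             mape_percent=float(np.median(np.abs(pe))),
                             mpe_percent=float(np.median(pe)),
                             rmspe_percent=float(math.sqrt(sq)),
                             r=r, n=len(meas), r_note=note)


@dataclass(frozen=True)
class FitMetrics:
    """Full simulated-vs-observed summary for one kinetic dataset."""

    auc_model: float
    auc_data: float
    auc_r: float
    mssd: float
    errors: PerformanceErrors


def fit_metrics(simulation, data: KineticDataset, series: str = "venous_blood",
                sim_unit: str = "mg/L") -> FitMetrics:
    pred = _predicted_at(simulation, data, series, sim_unit)
    obs = np.asarray(data.concentrations, dtype=float)
    auc_d = auc_trapezoid(data.times_h, obs)
    auc_m = auc_trapezoid(data.times_h, pred)
    return FitMetrics(auc_model=auc_m, auc_data=auc_d,
                      auc_r=auc_ratio(auc_m, auc_d),
                      mssd=float(np.mean((pred - obs) ** 2)),
                      errors=performance_errors(obs, pred))


# -- sensitivity ratios ----------------------------------------------------

@dataclass(frozen=True)
class SensitivityEntry:
    parameter: str
    metric: str
    sr: float
    delta: float


@dataclass(frozen=True)
class SensitivityReport:
    entries: tuple[SensitivityEntry, ...]
    failures: tuple[tuple[str, str, str], ...] = ()  # (parameter, metric, reason)


def sensitivity_ratio(run: Callable[[Mapping[str, float]], Mapping[str, float]],
                      params: Mapping[str, float], parameter: str, metric: str,
                      delta: float = 0.01, central: bool = False) -> float:
    """SR = (dY/Y)/(dX/X) for a relative perturbation ``delta`` of one input.

    Forward difference by default (X -> X(1+delta)); the central variant
    uses X(1 +/- delta).  A positive SR means the output increases with the
    input.
    """
    if parameter not in params:
        raise KeyError(f"unknown parameter {parameter!r}")
    if delta <= 0:
        raise DataError("perturbation fraction must be positive")
    x = params[parameter]
    if x == 0:
        raise DataError(f"cannot relatively perturb {parameter!r} = 0")
    y0 = float(run(dict(params))[metric])
    up = dict(params)
    up[parameter] = x * (1.0 + delta)
    y_up = float(run(up)[metric])
    if central:
        dn = dict(params)
        dn[parameter] = x * (1.0 - delta)
        y_dn = float(run(dn)[metric])
        if y0 == 0:
            raise DataError(f"baseline value of {metric!r} is zero; SR undefined")
        return ((y_up - y_dn) / y0) / (2.0 * delta)
    if y0 == 0:
        raise DataError(f"baseline value of {metric!r} is zero; SR undefined")
    return ((y_up - y0) / y0) / delta


def sensitivity_screen(run, params: Mapping[str, float],
                       parameters: Sequence[str], metrics: Sequence[str],
                       delta: float = 0.01, central: bool = False) -> SensitivityReport:
    """Full cross of parameter x metric SRs, sorted by |SR| descending.

    Individual pair failures are recorded in the report, not raised.
    """
    entries: list[SensitivityEntry] = []
    failures: list[tuple[str, str, str]] = []
    for pname in parameters:
        for metric in metrics:
            try:
                sr = sensitivity_ratio(run, params, pname, metric, delta=delta, central=central)
                entries.append(SensitivityEntry(parameter=pname, metric=metric,
                                                sr=sr, delta=delta))
            except Exception as exc:  # recorded, not fatal
                failures.append((pname, metric, str(exc)))
    entries.sort(key=lambda e: abs(e.sr), reverse=True)
    return SensitivityReport(entries=tuple(entries), failures=tuple(failures))
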