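"""Reading and writing the toolkit's CSV interchange formats."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .evaluation import KineticDataset
from .engine import SimulationResult


def write_timeseries_csv(result: SimulationResult, path) -> None:
    """Long format: time_h,compartment,quantity,unit,value."""
    result.to_frame().to_csv(path, index=False, float_format="%.10g")


def read_timeseries_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"time_h", "compartment", "quantity", "unit", "value"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"time-series CSV missing columns: {sorted(missing)}")
    return df


def read_kinetic_csv(path, label: str = "blood", citation: str | None = None) -> KineticDataset:
    """Observed kinetic data: columns time_h, concentration, unit."""
    df = pd.read_csv(path)
    required = {"time_h", "concentration", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"kinetic CSV missing columns: {sorted(missing)}")
    units = df["unit"].unique()
    if len(units) != 1:
        raise DataError(f"kinetic CSV mixes units: {list(units)}")
    return KineticDataset(times_h=df["time_h"].to_numpy(dtype=float),
                          concentrations=df["concentration"].to_numpy(dtype=float),
                          unit=str(units[0]), label=label, citation=citation)


def timeseries_series(df: pd.DataFrame, compartment: str):
    """Extract (times, values) for one compartment from a long-format frame."""
    sub = df[df["compartment"] == compartment].sort_values("time_h")
    if sub.empty:
        raise DataError(f"no series for compartment {compartment!r}")
    return sub["time_h"].to_numpy(dtype=float), sub["value"].to_numpy(dtype=float)
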