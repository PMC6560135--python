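"""Reading and writing the tidy delimited formats shared by all stages.

Time series are stored long-form with columns
``strain, condition, replicate, time_h, variable, value`` where
``variable`` is ``od600`` or a metabolite name and values carry the units
of the variable (OD600 or mM).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .growth_kinetics import GrowthCurve

TIMESERIES_COLUMNS = ["strain", "condition", "replicate", "time_h", "variable", "value"]


def write_timeseries(df: pd.DataFrame, path: str | Path) -> None:
    missing = set(TIMESERIES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"time-series table missing columns {sorted(missing)}")
    df.to_csv(path, index=False, columns=TIMESERIES_COLUMNS)


def read_timeseries(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TIMESERIES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def iter_replicates(df: pd.DataFrame) -> Iterable[tuple[tuple, pd.DataFrame]]:
    """Yield ((strain, condition, replicate), subtable) groups."""
    for key, sub in df.groupby(["strain", "condition", "replicate"], sort=True):
        yield key, sub


def curve_from_tidy(sub: pd.DataFrame, addition_time: float | None = None) -> GrowthCurve:
    """Extract the OD600 series of one replicate subtable as a GrowthCurve."""
    od = sub[sub["variable"] == "od600"].sort_values("time_h")
    if od.empty:
        raise ValueError("replicate subtable has no od600 rows")
    strain, condition, replicate = (
        od["strain"].iloc[0], od["condition"].iloc[0], int(od["replicate"].iloc[0])
    )
    return GrowthCurve(
        times=od["time_h"].to_numpy(dtype=float),
        od=od["value"].to_numpy(dtype=float),
        strain=str(strain),
        condition=str(condition),
        replicate=replicate,
        addition_time=addition_time,
    )


def metabolite_series(sub: pd.DataFrame, name: str) -> tuple[np.ndarray, np.ndarray]:
    """(times, concentrations) of one metabolite from a replicate subtable."""
    m = sub[sub["variable"] == name].sort_values("time_h")
    if m.empty:
        raise ValueError(f"no rows for metabolite {name!r}")
    return m["time_h"].to_numpy(dtype=float), m["value"].to_numpy(dtype=float)
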