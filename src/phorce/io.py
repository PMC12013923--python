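"""Reading and writing plate time series, layouts and results tables.

The interchange format is a long-format table with columns ``time_h``,
``well``, ``signal`` (optional ``readout``); a wide format (one column per
well) is auto-detected.  Times are hours everywhere; minute- or
second-resolved files are accepted only through an explicit ``time_unit``
flag, never by guessing.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .curves import GrowthCurve
from .synth import PlateDataset

__all__ = [
    "SchemaError",
    "read_layout",
    "read_plate_timeseries",
    "write_curves",
    "write_layout",
    "write_dataset",
]

logger = logging.getLogger("phorce")

_TIME_FACTORS = {"h": 1.0, "min": 1.0 / 60.0, "s": 1.0 / 3600.0}
_LAYOUT_COLUMNS = {"well", "b0", "phage", "stock_dilution", "drug", "drug_conc", "role"}
_ROLES = {"phage_well", "no_phage_control", "calibration"}


class SchemaError(ValueError):
    """An input table does not match the expected schema."""


def read_layout(path: Union[str, Path, pd.DataFrame]) -> pd.DataFrame:
    """Load and validate a plate-layout table."""
    layout = path if isinstance(path, pd.DataFrame) else pd.read_csv(path)
    missing = {"well", "role"} - set(layout.columns)
    if missing:
        raise SchemaError(
            f"layout is missing columns {sorted(missing)}; expected at least "
            f"{sorted(_LAYOUT_COLUMNS)}"
        )
    bad_roles = set(layout["role"].dropna()) - _ROLES
    if bad_roles:
        raise SchemaError(f"unknown layout roles {sorted(bad_roles)}; expected {sorted(_ROLES)}")
    if layout["well"].duplicated().any():
        dupes = layout.loc[layout["well"].duplicated(), "well"].tolist()
        raise SchemaError(f"duplicate wells in layout: {dupes}")
    return layout


def _is_long(df: pd.DataFrame) -> bool:
    cols = set(df.columns)
    return {"well", "signal"} <= cols and ("time_h" in cols or "time" in cols)


def read_plate_timeseries(
    path: Union[str, Path],
    layout: Optional[Union[str, Path, pd.DataFrame]] = None,
    time_unit: str = "h",
) -> List[GrowthCurve]:
    """Read per-well growth curves, optionally joined to a plate layout.

    Long format needs columns ``time_h`` (or ``time`` + ``time_unit``),
    ``well`` and ``signal``; any other shape whose first column is the time
    axis is treated as wide format with one column per well.  Wells absent
    from the layout are reported and returned without condition metadata.
    """
    if time_unit not in _TIME_FACTORS:
        raise ValueError(f"time_unit must be one of {sorted(_TIME_FACTORS)}")
    df = pd.read_csv(path)
    if df.empty:
        return []
    if _is_long(df):
        time_col = "time_h" if "time_h" in df.columns else "time"
        long = df.rename(columns={time_col: "time"})
    else:
        time_col = df.columns[0]
        if time_col not in ("time_h", "time"):
            raise SchemaError(
                "expected long format (columns time_h, well, signal) or wide format "
                f"with a leading time_h/time column; got columns {list(df.columns)}"
            )
        long = df.melt(id_vars=[time_col], var_name="well", value_name="signal")
        long = long.rename(columns={time_col: "time"}).dropna(subset=["signal"])
    factor = 1.0 if time_col == "time_h" else _TIME_FACTORS[time_unit]

    layout_df = read_layout(layout) if layout is not None else None
    layout_index = (
        layout_df.set_index("well") if layout_df is not None else None
    )
    unknown = []
    curves = []
    for well, group in long.groupby("well", sort=True):
        times = group["time"].to_numpy(dtype=float) * factor
        if np.any(np.diff(times) <= 0):
            raise SchemaError(f"non-monotone time axis in well {well!r}")
        readout = (
            str(group["readout"].iloc[0]) if "readout" in group.columns else "bioluminescence"
        )
        condition = None
        if layout_index is not None:
            if well in layout_index.index:
                condition = layout_index.loc[well].to_dict()
                condition["well"] = well
            else:
                unknown.append(well)
        curves.append(
            GrowthCurve(
                times=times,
                signal=group["signal"].to_numpy(dtype=float),
                readout=readout,
                well_id=str(well),
                condition=condition,
            )
        )
    if unknown:
        warnings.warn(f"wells missing from layout: {unknown}", stacklevel=2)
    return curves


def write_curves(
    curves: Sequence[GrowthCurve], path: Union[str, Path], fmt: str = "long"
) -> None:
    """Write curves as a long- or wide-format CSV."""
    if fmt == "long":
        frames = [
            pd.DataFrame(
                {
                    "time_h": c.times,
                    "well": c.well_id,
                    "signal": c.signal,
                    "readout": c.readout,
                }
            )
            for c in curves
        ]
        out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["time_h", "well", "signal", "readout"]
        )
    elif fmt == "wide":
        out = pd.DataFrame({"time_h": curves[0].times})
        for c in curves:
            if len(c) != len(curves[0]) or not np.allclose(c.times, curves[0].times):
                raise ValueError("wide format requires a shared time grid")
            out[c.well_id] = c.signal
    else:
        raise ValueError(f"unknown format {fmt!r}")
    out.to_csv(path, index=False)


def write_layout(layout: pd.DataFrame, path: Union[str, Path]) -> None:
    layout.to_csv(path, index=False)


def write_dataset(dataset: PlateDataset, out_dir: Union[str, Path]) -> dict:
    """Write a synthetic dataset (time series, layout, truth manifest)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "timeseries": out / "timeseries.csv",
        "layout": out / "layout.csv",
        "manifest": out / "manifest.csv",
    }
    write_curves(dataset.curves, paths["timeseries"])
    write_layout(dataset.layout, paths["layout"])
    dataset.manifest.to_csv(paths["manifest"], index=False)
    return {k: str(v) for k, v in paths.items()}
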