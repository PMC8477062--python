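"""Readers and writers for the pipeline's plain-text formats.

CSV schemas
-----------
inventory : plot_id, tree_id, x_m, y_m, dbh_cm, height_m, cored, planting_year
rings     : core_id, tree_id, plot_id, year, width_mm   (long format)
climate   : year, month, tmean_c, prcp_mm, rh_pct [, tmax_c, tmin_c,
            wind_ms, pres_hpa]

Ring widths are also supported in the Tucson decadal (.rwl) exchange
format: fixed-width lines carrying the series id, the decade's first year,
and up to ten values in 0.01 mm units, with 999 terminating a series.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .climate import ClimateSeries
from .competition import StandInventory, TREE_COLUMNS
from .rings import RingSeries

__all__ = [
    "read_inventory_csv", "write_inventory_csv",
    "read_rings_csv", "write_rings_csv",
    "read_climate_csv", "write_climate_csv",
    "read_rwl", "write_rwl",
]


# ---------------------------------------------------------------------------
# inventory
# ---------------------------------------------------------------------------

def read_inventory_csv(path, plot_width_m: float = 30.0,
                       plot_height_m: float = 30.0) -> dict[str, StandInventory]:
    """Read an inventory CSV into one StandInventory per plot.

    Plot rectangle dimensions are not part of the schema; pass them (all
    plots of a study share the sampling-plot size).
    """
    df = pd.read_csv(path)
    required = ["plot_id", "tree_id", "x_m", "y_m", "dbh_cm", "height_m",
                "cored", "planting_year"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: inventory missing columns {missing}")
    stands = {}
    for plot_id, sub in df.groupby("plot_id"):
        py = sub["planting_year"].unique()
        if len(py) != 1:
            raise ValueError(f"plot {plot_id}: multiple planting years {py}")
        trees = sub[list(TREE_COLUMNS)].copy()
        trees["cored"] = trees["cored"].astype(bool)
        trees["tree_id"] = trees["tree_id"].astype(str)
        stands[str(plot_id)] = StandInventory(
            plot_id=str(plot_id), width_m=plot_width_m, height_m=plot_height_m,
            planting_year=int(py[0]), trees=trees.reset_index(drop=True))
    return stands


def write_inventory_csv(stands: dict[str, StandInventory], path) -> None:
    rows = []
    for stand in stands.values():
        t = stand.trees.copy()
        t.insert(0, "plot_id", stand.plot_id)
        t["cored"] = t["cored"].astype(int)
        t["planting_year"] = stand.planting_year
        rows.append(t)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# rings (long CSV)
# ---------------------------------------------------------------------------

def read_rings_csv(path) -> list[RingSeries]:
    df = pd.read_csv(path)
    required = ["core_id", "year", "width_mm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: rings missing columns {missing}")
    keys = ["plot_id", "core_id"] if "plot_id" in df.columns else ["core_id"]
    out = []
    for key, sub in df.groupby(keys, sort=False):
        core_id = key[-1] if isinstance(key, tuple) else key
        sub = sub.sort_values("year")
        years = sub["year"].to_numpy(dtype=int)
        if np.any(np.diff(years) != 1):
            raise ValueError(f"core {core_id}: years not contiguous")
        out.append(RingSeries(
            core_id=str(core_id),
            tree_id=str(sub["tree_id"].iloc[0]) if "tree_id" in sub else str(core_id),
            plot_id=str(sub["plot_id"].iloc[0]) if "plot_id" in sub else "",
            first_year=int(years[0]),
            widths=sub["width_mm"].to_numpy(dtype=float)))
    return out


def write_rings_csv(series: list[RingSeries], path) -> None:
    rows = []
    for s in series:
        rows.append(pd.DataFrame({
            "core_id": s.core_id, "tree_id": s.tree_id, "plot_id": s.plot_id,
            "year": s.years, "width_mm": s.widths}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# climate CSV
# ---------------------------------------------------------------------------

def read_climate_csv(path, latitude: float = 45.0,
                     allow_gaps: bool = False) -> ClimateSeries:
    """Read the climate CSV; optionally interpolate gaps ≤ 2 months."""
    df = pd.read_csv(path)
    value_cols = [c for c in df.columns if c not in ("year", "month")]
    if df[value_cols].isna().any().any():
        if not allow_gaps:
            bad = df[df[value_cols].isna().any(axis=1)].index[0]
            raise ValueError(f"{path}: missing value at row {bad + 2} "
                             "(pass allow_gaps=True to interpolate short gaps)")
        for c in value_cols:
            runs = df[c].isna().astype(int).groupby(df[c].notna().cumsum()).sum()
            if (runs > 2).any():
                raise ValueError(f"{path}: gap longer than 2 months in {c}")
            df[c] = df[c].interpolate(limit=2, limit_direction="both")
    return ClimateSeries(df, latitude=latitude)


def write_climate_csv(series: ClimateSeries, path) -> None:
    series.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Tucson decadal .rwl
# ---------------------------------------------------------------------------

_RWL_STOP = 999
_UNITS = 100.0  # 0.01 mm


def write_rwl(series: list[RingSeries], path) -> None:
    """Write ring series in Tucson decadal format (0.01 mm, 999 stop)."""
    lines = []
    for s in series:
        sid = s.core_id[:8]
        vals = list(np.round(s.widths * _UNITS).astype(int))
        years = list(s.years)
        i = 0
        while i < len(vals):
            year = years[i]
            decade_end = (year // 10) * 10 + 9
            take = min(decade_end - year + 1, len(vals) - i)
            chunk = vals[i:i + take]
            fields = "".join(f"{v:6d}" for v in chunk)
            if i + take == len(vals):
                fields += f"{_RWL_STOP:6d}"
            lines.append(f"{sid:<8s}{year:4d}{fields}")
            i += take
    Path(path).write_text("\n".join(lines) + "\n")


def read_rwl(path) -> list[RingSeries]:
    """Read a Tucson decadal .rwl file.

    The conventional 999 (or -9999) end marker terminates a series; by
    convention a trailing value of exactly 999 is always read as the
    terminator, so a true final ring of 9.99 mm cannot be represented.
    """
    series: dict[str, tuple[int, list[float]]] = {}
    order: list[str] = []
    for raw in Path(path).read_text().splitlines():
        if not raw.strip():
            continue
        sid = raw[:8].strip()
        rest = raw[8:].split()
        year = int(rest[0])
        vals = rest[1:]
        if sid not in series:
            series[sid] = (year, [])
            order.append(sid)
        for tok in vals:
            v = int(tok)
            if v in (_RWL_STOP, -9999):
                break
            series[sid][1].append(v / _UNITS)
    out = []
    for sid in order:
        first, widths = series[sid]
        out.append(RingSeries(core_id=sid, tree_id=sid, plot_id="",
                              first_year=first,
                              widths=np.asarray(widths, dtype=float)))
    return out
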