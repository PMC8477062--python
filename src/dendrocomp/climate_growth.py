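"""Monthly climate–growth correlation screen.

Residual chronologies are correlated cell-by-cell against monthly climate
variables over a dendroclimatological window running from October of the
year preceding ring formation ("P_Oct") through September of the ring year
("C_Sep"); the window end is configurable up to the current October. Each
cell gets a Pearson r with its exact t-distribution p-value and the usual
per-cell significance stars.

No multiple-testing correction is applied by default: the screen mimics the
conventional per-cell starring of correlation heat maps, where each of the
~84 cells is tested at its nominal level. Under a null of independence
about 5% of cells will be starred by chance; treat the screen as a ranking
device, not a family-wise inference. A Bonferroni option is available for
the cautious.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .climate import ClimateSeries, spei, vpd_from_t_rh

__all__ = ["lag_align", "correlate", "select_significant", "month_labels"]

_MONTH_ABBR = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
               "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]

BASE_VARIABLES = ("prcp", "tmean", "rh", "vpd", "spei1")


def month_labels(window_end: str = "C_Sep") -> list[str]:
    """Ordered labels P_Oct..window_end (12 cells; 13 when ending C_Oct)."""
    labels = [f"P_{m}" for m in ("Oct", "Nov", "Dec")]
    if window_end == "C_Sep":
        last = 9
    elif window_end == "C_Oct":
        last = 10
    else:
        raise ValueError("window_end must be 'C_Sep' or 'C_Oct'")
    labels += [f"C_{_MONTH_ABBR[m - 1]}" for m in range(1, last + 1)]
    return labels


def _variable_table(climate: ClimateSeries) -> pd.DataFrame:
    """Long table (year, month, variable columns) of screen variables."""
    df = climate.data.copy()
    out = pd.DataFrame({"year": df["year"], "month": df["month"]})
    out["prcp"] = df["prcp_mm"].to_numpy(dtype=float)
    out["tmean"] = df["tmean_c"].to_numpy(dtype=float)
    out["rh"] = df["rh_pct"].to_numpy(dtype=float)
    out["vpd"] = vpd_from_t_rh(df["tmean_c"].to_numpy(dtype=float),
                               df["rh_pct"].to_numpy(dtype=float))
    out["spei1"] = spei(climate, scale=1)
    for extra, col in (("tmax", "tmax_c"), ("tmin", "tmin_c")):
        if col in df.columns:
            out[extra] = df[col].to_numpy(dtype=float)
    return out


def lag_align(climate: ClimateSeries, years, window_end: str = "C_Sep",
              variables: tuple | None = None) -> pd.DataFrame:
    """Design table of monthly predictors per ring year.

    Row Y holds every screen variable at months Oct(Y−1) … Sep(Y) (or
    Oct(Y)); columns are a (variable, month-label) MultiIndex. Rows with
    any missing month are dropped; the climate record must reach back to
    October of the year before the first ring year.
    """
    years = np.asarray(sorted(years), dtype=int)
    labels = month_labels(window_end)
    table = _variable_table(climate)
    if variables is None:
        variables = [v for v in list(BASE_VARIABLES) + ["tmax", "tmin"]
                     if v in table.columns]

    first_needed = years[0] - 1
    have = set(zip(table["year"], table["month"]))
    if (first_needed, 10) not in have:
        raise ValueError(
            f"climate must start by October {first_needed} to cover ring year "
            f"{years[0]} (window begins the previous October)")

    cols = {}
    for var in variables:
        pivot = table.pivot(index="year", columns="month", values=var)
        for lab in labels:
            prefix, mon = lab.split("_")
            m = _MONTH_ABBR.index(mon) + 1
            offset = -1 if prefix == "P" else 0
            series = pivot.reindex(years + offset)[m] if m in pivot.columns \
                else pd.Series(np.nan, index=years + offset)
            cols[(var, lab)] = series.to_numpy()
    design = pd.DataFrame(cols, index=years)
    design.columns = pd.MultiIndex.from_tuples(design.columns,
                                               names=["variable", "month"])
    design = design.dropna(axis=0, how="any")
    if design.empty:
        raise ValueError("no ring year has a complete climate window")
    return design


def correlate(chronology: pd.Series, design: pd.DataFrame,
              min_years: int = 15) -> pd.DataFrame:
    """Pearson r (exact t-distribution p) per (variable, month) cell.

    Returns a long frame with columns ``variable, month, r, p, n, flag``;
    flags: '**' p<0.01, '*' p<0.05, 'ns' otherwise, 'undef' for
    zero-variance cells.
    """
    common = design.index.intersection(chronology.dropna().index)
    if len(common) < min_years:
        raise ValueError(f"need >= {min_years} overlapping years, have {len(common)}")
    y = chronology.loc[common].to_numpy(dtype=float)
    rows = []
    for (var, mon) in design.columns:
        x = design.loc[common, (var, mon)].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((var, mon, np.nan, np.nan, len(common), "undef"))
            continue
        r, p = stats.pearsonr(x, y)
        flag = "**" if p < 0.01 else "*" if p < 0.05 else "ns"
        rows.append((var, mon, float(r), float(p), len(common), flag))
    return pd.DataFrame(rows, columns=["variable", "month", "r", "p", "n", "flag"])


def select_significant(table: pd.DataFrame, alpha: float = 0.05,
                       top: int = 4, bonferroni: bool = False) -> pd.DataFrame:
    """Rank significant cells by |r| and return the strongest ``top``.

    Ties in |r| keep the table's month order (stable sort). With
    ``bonferroni=True`` the level is divided by the number of tested cells.
    An empty result (nothing significant) is returned with a warning.
    """
    tested = table[table["flag"] != "undef"]
    level = alpha / len(tested) if bonferroni else alpha
    sig = tested[tested["p"] < level].copy()
    if sig.empty:
        warnings.warn("no climate cell is significant at the requested level")
        return sig
    sig = sig.sort_values("r", key=np.abs, ascending=False, kind="stable")
    return sig.head(top).reset_index(drop=True)
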