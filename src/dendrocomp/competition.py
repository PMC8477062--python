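"""Distance-dependent competition and its retroactive reconstruction.

The Hegyi competition index of a subject tree i is

    CI_i = Σ_j (D_j / D_i) · (1 / d_ij)

summed over all neighbours j within a fixed search radius (8 m by default),
where D is DBH (cm) and d_ij the stem-to-stem distance (m). Stand-level
competition classes follow the conventional cut-points: low (CI < 1),
medium (1 ≤ CI < 3), high (CI ≥ 3).

Because annual DBH records do not exist for the studied stands, past
diameters are reconstructed from the cored trees' ring series: each cored
tree yields an annual growth-rate series GR_k = RI_k / RI_total, the plot
growth rate is the renormalized mean over cored trees, non-cored diameters
are back-cast by multiplying the observed DBH by the cumulative plot growth
rate, cored diameters by subtracting their own radial increments, and the
Hegyi index is then evaluated year by year on the reconstructed stand.

Two assumptions are inherited from the reconstruction method: (i) the
over-bark diameter growth *rate* equals the under-bark radial growth rate
(rates map, not magnitudes — hence non-cored trees use the rate path only),
and (ii) the plot is a single even-aged cohort with no mortality during the
reconstructed period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rings import RingSeries

__all__ = [
    "StandInventory",
    "CompetitionResult",
    "hegyi_ci",
    "hegyi_all",
    "classify_ci",
    "growth_rate_series",
    "plot_growth_rate",
    "backcast_dbh",
    "annual_ci",
    "reconstruct_annual_ci",
]

DEFAULT_RADIUS_M = 8.0
CI_CLASS_BOUNDS = (1.0, 3.0)
MIN_DBH_CM = 1.0  # below this a reconstructed stem has not reached breast height

TREE_COLUMNS = ("tree_id", "x_m", "y_m", "dbh_cm", "height_m", "cored")


@dataclass
class StandInventory:
    """Spatially explicit inventory of one rectangular even-aged plot.

    ``trees`` holds one row per stem with columns
    ``tree_id, x_m, y_m, dbh_cm, height_m, cored``. Positions must lie
    inside the plot rectangle, DBH must be positive and ids unique.
    """

    plot_id: str
    width_m: float
    height_m: float
    planting_year: int
    trees: pd.DataFrame

    def __post_init__(self) -> None:
        if self.width_m <= 0 or self.height_m <= 0:
            raise ValueError("plot dimensions must be positive")
        df = self.trees.reset_index(drop=True)
        missing = [c for c in TREE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"inventory missing columns: {missing}")
        if df["tree_id"].duplicated().any():
            raise ValueError("duplicate tree ids")
        x = df["x_m"].to_numpy(dtype=float)
        y = df["y_m"].to_numpy(dtype=float)
        if np.any((x < 0) | (x > self.width_m) | (y < 0) | (y > self.height_m)):
            raise ValueError("tree positions outside the plot")
        if np.any(df["dbh_cm"].to_numpy(dtype=float) <= 0):
            raise ValueError("DBH must be positive")
        self.trees = df

    def __len__(self) -> int:
        return len(self.trees)

    def positions(self) -> np.ndarray:
        return self.trees[["x_m", "y_m"]].to_numpy(dtype=float)

    def distance_matrix(self) -> np.ndarray:
        p = self.positions()
        diff = p[:, None, :] - p[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))

    def density_per_ha(self) -> float:
        return len(self) / (self.width_m * self.height_m / 1e4)


@dataclass
class CompetitionResult:
    tree_id: str
    ci: float
    n_competitors: int
    ci_class: str
    edge: bool  # True when the search disc leaves the plot


def classify_ci(ci: float) -> str:
    """Competition class from the standard cut-points (half-open intervals).

    low: CI < 1; medium: 1 ≤ CI < 3; high: CI ≥ 3.
    """
    if ci < 0:
        raise ValueError("CI must be non-negative")
    lo, hi = CI_CLASS_BOUNDS
    if ci < lo:
        return "low"
    if ci < hi:
        return "medium"
    return "high"


def _edge_flags(stand: StandInventory, radius: float) -> np.ndarray:
    x = stand.trees["x_m"].to_numpy(dtype=float)
    y = stand.trees["y_m"].to_numpy(dtype=float)
    return ((x < radius) | (x > stand.width_m - radius)
            | (y < radius) | (y > stand.height_m - radius))


def _disc_area_fraction(x: float, y: float, w: float, h: float,
                        radius: float, ngrid: int = 64) -> float:
    """Fraction of the search disc inside the plot (deterministic grid)."""
    g = (np.arange(ngrid) + 0.5) / ngrid * 2 * radius - radius
    gx, gy = np.meshgrid(x + g, y + g)
    inside_disc = (gx - x) ** 2 + (gy - y) ** 2 <= radius**2
    inside_plot = (gx >= 0) & (gx <= w) & (gy >= 0) & (gy <= h)
    return float((inside_disc & inside_plot).sum() / inside_disc.sum())


def _ci_matrix(dbh: np.ndarray, dist: np.ndarray, radius: float) -> np.ndarray:
    """Vector of Hegyi CIs for all trees; dist is the full distance matrix."""
    n = len(dbh)
    within = (dist <= radius) & ~np.eye(n, dtype=bool)
    if np.any(within & (dist == 0)):
        raise ValueError("coincident tree positions within the search radius")
    with np.errstate(divide="ignore"):
        inv_d = np.where(within, 1.0 / np.where(dist > 0, dist, 1.0), 0.0)
    ratio = dbh[None, :] / dbh[:, None]  # D_j / D_i at [i, j]
    return (ratio * inv_d * within).sum(axis=1)


def hegyi_all(stand: StandInventory, radius: float = DEFAULT_RADIUS_M,
              edge_correct: bool = False) -> pd.DataFrame:
    """Hegyi CI for every tree in the stand.

    Returns a frame with columns ``tree_id, ci, n_competitors, ci_class,
    edge``. With ``edge_correct=True`` the CI of edge trees is divided by
    the fraction of the search disc inside the plot (a linear-expansion
    correction); the default applies no correction and only flags them.
    """
    dbh = stand.trees["dbh_cm"].to_numpy(dtype=float)
    dist = stand.distance_matrix()
    ci = _ci_matrix(dbh, dist, radius)
    ncomp = ((dist <= radius) & ~np.eye(len(dbh), dtype=bool)).sum(axis=1)
    edge = _edge_flags(stand, radius)
    if edge_correct:
        for i in np.where(edge)[0]:
            frac = _disc_area_fraction(stand.trees.at[i, "x_m"],
                                       stand.trees.at[i, "y_m"],
                                       stand.width_m, stand.height_m, radius)
            if frac > 0:
                ci[i] = ci[i] / frac
    return pd.DataFrame({
        "tree_id": stand.trees["tree_id"],
        "ci": ci,
        "n_competitors": ncomp,
        "ci_class": [classify_ci(c) for c in ci],
        "edge": edge,
    })


def hegyi_ci(stand: StandInventory, tree_id: str,
             radius: float = DEFAULT_RADIUS_M,
             edge_correct: bool = False) -> CompetitionResult:
    """Hegyi CI of one subject tree."""
    table = hegyi_all(stand, radius=radius, edge_correct=edge_correct)
    row = table[table["tree_id"] == tree_id]
    if row.empty:
        raise KeyError(f"tree {tree_id!r} not in stand {stand.plot_id!r}")
    r = row.iloc[0]
    return CompetitionResult(tree_id=tree_id, ci=float(r["ci"]),
                             n_competitors=int(r["n_competitors"]),
                             ci_class=str(r["ci_class"]), edge=bool(r["edge"]))


# ---------------------------------------------------------------------------
# growth-rate series and DBH back-casting
# ---------------------------------------------------------------------------

def growth_rate_series(core: RingSeries) -> pd.Series:
    """Annual growth-rate series GR_k = RI_k / Σ RI (sums to 1)."""
    total = core.widths.sum()
    if total <= 0:
        raise ValueError("zero total radial increment")
    return pd.Series(core.widths / total, index=core.years, name=core.tree_id)


def plot_growth_rate(rates: list[pd.Series], min_trees: int = 3) -> pd.Series:
    """Mean plot growth rate: year-wise mean over cored trees, renormalized.

    The series are trimmed to their common year span before averaging, and
    the result is renormalized to sum to 1 so it remains a valid cumulative
    growth fraction after trimming.
    """
    if len(rates) < min_trees:
        raise ValueError(f"plot growth rate needs >= {min_trees} cored trees")
    table = pd.concat(list(rates), axis=1).dropna()
    if table.empty:
        raise ValueError("cored trees share no common year span")
    mean = table.mean(axis=1)
    return mean / mean.sum()


def backcast_dbh(dbh_obs_cm: float, plot_gr: pd.Series,
                 widths_mm: pd.Series | None = None,
                 min_dbh_cm: float = MIN_DBH_CM) -> pd.Series:
    """Reconstruct the annual end-of-year DBH series of one tree (cm).

    Non-cored path (``widths_mm is None``): D_k = D_obs · Σ_{j≤k} GR_j,
    scaling the observed diameter by the cumulative plot growth rate.
    Cored path: D_k = D_obs − 2·Σ_{j>k} width_j / 10, subtracting the tree's
    own future radial increments (mm → cm, radius → diameter). Both paths
    close exactly on the observed DBH in the final year. Values that fall
    below ``min_dbh_cm`` (stem not yet at breast height) are floored there
    and the first unfloored year is recorded in ``attrs['first_valid_year']``.
    """
    if dbh_obs_cm <= 0:
        raise ValueError("observed DBH must be positive")
    if widths_mm is None:
        cum = plot_gr.sort_index().cumsum()
        raw = dbh_obs_cm * cum
        raw.iloc[-1] = dbh_obs_cm  # exact closure, no float residue
        years = raw.index
    else:
        w = widths_mm.sort_index()
        future = w[::-1].cumsum()[::-1].shift(-1, fill_value=0.0)
        raw = dbh_obs_cm - 2.0 * future / 10.0
        years = raw.index
    if (raw <= 0).any():
        warnings.warn("reconstructed diameter non-positive before flooring")
    valid = raw >= min_dbh_cm
    out = raw.clip(lower=min_dbh_cm)
    out.attrs["first_valid_year"] = int(years[valid.to_numpy()][0]) if valid.any() else None
    return out


def annual_ci(stand: StandInventory, dbh_history: pd.DataFrame, tree_id: str,
              radius: float = DEFAULT_RADIUS_M,
              min_dbh_cm: float = MIN_DBH_CM,
              include_cored_neighbors: bool = True) -> pd.Series:
    """Hegyi CI of a cored subject evaluated on reconstructed diameters.

    ``dbh_history`` is a years × tree_id frame of reconstructed DBHs. The
    competitor set is fixed by geometry (all neighbours within ``radius``);
    years in which the subject or any competitor is below ``min_dbh_cm``
    are undefined (NaN) — DBH is not meaningful before breast height.
    Cored neighbours enter the competitor set by default (their back-cast
    histories are the best known); ``include_cored_neighbors=False``
    restricts competitors to non-cored trees.
    """
    ids = stand.trees["tree_id"].tolist()
    if tree_id not in ids:
        raise KeyError(f"tree {tree_id!r} not in stand")
    i = ids.index(tree_id)
    dist = stand.distance_matrix()[i]
    cored = stand.trees["cored"].to_numpy(dtype=bool)
    within = (dist <= radius) & (np.arange(len(ids)) != i)
    if not include_cored_neighbors:
        within &= ~cored
    comp_ids = [ids[j] for j in np.where(within)[0]]
    comp_dist = dist[within]
    if np.any(comp_dist == 0):
        raise ValueError("coincident tree positions within the search radius")

    subject = dbh_history[tree_id]
    if not comp_ids:
        return pd.Series(0.0, index=subject.index, name=tree_id)
    comp = dbh_history[comp_ids]
    ci = (comp.div(subject, axis=0) / comp_dist).sum(axis=1)
    undefined = (subject < min_dbh_cm) | (comp < min_dbh_cm).any(axis=1)
    ci[undefined] = np.nan
    ci.name = tree_id
    return ci


def reconstruct_annual_ci(stand: StandInventory, cores: dict[str, RingSeries],
                          radius: float = DEFAULT_RADIUS_M,
                          min_dbh_cm: float = MIN_DBH_CM,
                          include_cored_neighbors: bool = True,
                          allow_ingrowth: bool = False,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full retroactive reconstruction for one plot.

    ``cores`` maps cored tree ids to their (tree-level) ring-width series.
    Returns ``(dbh_history, ci_history)``: years × tree frames of
    reconstructed DBH for every tree and of annual CI for every cored tree.

    The even-aged/no-mortality assumption is enforced: cored series must
    start no earlier than the planting year; series implying in-growth
    (first measured ring more than 5 years after planting) are rejected
    unless ``allow_ingrowth=True``.
    """
    for tid, core in cores.items():
        if core.first_year < stand.planting_year:
            raise ValueError(f"core {tid} predates the planting year")
        if core.first_year > stand.planting_year + 5 and not allow_ingrowth:
            raise ValueError(
                f"core {tid} starts {core.first_year - stand.planting_year} years "
                "after planting; pass allow_ingrowth=True to accept")

    rates = [growth_rate_series(c) for c in cores.values()]
    gr = plot_growth_rate(rates)

    hist = {}
    for _, row in stand.trees.iterrows():
        tid = row["tree_id"]
        dbh = float(row["dbh_cm"])
        if tid in cores:
            w = pd.Series(cores[tid].widths, index=cores[tid].years)
            w = w.reindex(gr.index).dropna()
            hist[tid] = backcast_dbh(dbh, gr, widths_mm=w, min_dbh_cm=min_dbh_cm)
        else:
            hist[tid] = backcast_dbh(dbh, gr, min_dbh_cm=min_dbh_cm)
    dbh_history = pd.DataFrame(hist).dropna()

    ci_cols = {}
    for tid in cores:
        ci_cols[tid] = annual_ci(stand, dbh_history, tid, radius=radius,
                                 min_dbh_cm=min_dbh_cm,
                                 include_cored_neighbors=include_cored_neighbors)
    ci_history = pd.DataFrame(ci_cols)
    return dbh_history, ci_history
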