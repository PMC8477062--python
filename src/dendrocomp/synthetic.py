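"""Synthetic stands, climates, and ring series with known ground truth.

No field data are released for the studied plantations, so every downstream
stage is exercised on simulated inputs whose generating process is known
exactly. The generator emulates the study design: 30 × 30 m even-aged
plots at low/medium/high planting densities, a semi-arid monthly climate
(precipitation peaking in July–August, <500 mm/yr) into which multi-year
droughts can be imposed, and radial growth driven by three causes —

* a negative-exponential cambial-age trend ``A(age)``,
* a growing-season moisture signal (the z-score of the April–October
  climatic water balance of the generated record itself),
* a competition penalty proportional to the tree's *true* annual Hegyi
  index, recomputed every year from the simulated diameters.

Ring width of tree i in year t is

    w_it = A(age_t) · exp(β·z_t − γ·CI_it − λ·CI_it·L_t + ε_it)

with ε_it ~ N(0, σ²) from a per-tree random stream, and L_t an indicator
for drought years and the ``legacy_years`` following them. The λ term is a
drought-legacy × competition interaction: crowded trees recover less after
a drought, which is the density-dependent vulnerability the resilience
stage is meant to detect. DBH accumulates 2 × width from a 0.5 cm seedling
caliper, so the final diameter closes exactly on the ring sums.

Random streams are split per plot, per tree and per substage with
``numpy.random.SeedSequence`` so the same configuration is bit-reproducible
and adding trees does not perturb existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .climate import ClimateSeries
from .competition import StandInventory, _ci_matrix
from .rings import RingSeries

__all__ = [
    "SimulationConfig",
    "GrowthSimulation",
    "SiteSimulation",
    "gen_climate",
    "gen_stand",
    "gen_growth",
    "simulate_plot",
    "simulate_site",
]

INITIAL_DIAMETER_CM = 0.5  # seedling caliper at planting; avoids zero division


@dataclass
class SimulationConfig:
    """Study conditions for one simulated plot and its climate.

    Growth-model sensitivities are on the log ring-width scale:
    ``beta_climate`` per unit of growing-season moisture z-score,
    ``gamma_competition`` and ``drought_legacy`` per Hegyi CI unit.
    ``drought_years`` lists imposed droughts as ``(start_year, duration,
    severity)``; severity scales growing-season precipitation by
    ``exp(−severity)``, so severity ≈ 2 removes ~86% of it.
    """

    plot_width: float = 30.0
    plot_height: float = 30.0
    density: float | None = 600.0          # trees/ha; alternative to n_trees
    n_trees: int | None = None
    planting_year: int = 1975
    n_years: int = 45
    beta_climate: float = 0.30
    gamma_competition: float = 0.06
    sigma_noise: float = 0.10
    drought_years: tuple = ((1990, 1, 2.0), (1999, 2, 2.5), (2010, 1, 2.0))
    drought_legacy: float = 0.08
    legacy_years: int = 2
    legacy_trigger_z: float = -1.3    # realized gs moisture z below this starts a legacy
    cored_fraction: float = 0.5
    seed: int = 0
    # climate shape parameters
    latitude: float = 42.5
    climate_spinup_years: int = 6
    t_base: float = 7.0
    t_amp: float = 15.0
    t_trend: float = 0.0          # °C per year
    t_noise_sd: float = 1.0
    p_annual_mm: float = 440.0
    p_shape: float = 4.0          # gamma shape of monthly precipitation
    rh_base: float = 55.0
    rh_amp: float = 12.0
    rh_noise_sd: float = 4.0
    # age-trend parameters (mm/yr)
    width_young: float = 3.5
    width_asymptote: float = 0.8
    age_tau: float = 12.0

    def __post_init__(self) -> None:
        if self.plot_width <= 0 or self.plot_height <= 0:
            raise ValueError("plot dimensions must be positive")
        if self.n_years < 10:
            raise ValueError("n_years must be >= 10")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be >= 0")
        if self.n_trees is None and self.density is None:
            raise ValueError("give density or n_trees")
        if self.density is not None and not 100 <= self.density <= 2000:
            raise ValueError("density must lie in [100, 2000] trees/ha")
        for start, duration, severity in self.drought_years:
            if severity <= 0:
                raise ValueError("drought severity must be > 0")
            if duration < 1:
                raise ValueError("drought duration must be >= 1 year")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.planting_year, self.planting_year + self.n_years)

    def resolved_n_trees(self) -> int:
        if self.n_trees is not None:
            return int(self.n_trees)
        area_ha = self.plot_width * self.plot_height / 1e4
        return int(math.floor(area_ha * self.density))

    def imposed_drought_years(self) -> set[int]:
        out: set[int] = set()
        for start, duration, _ in self.drought_years:
            out.update(range(start, start + duration))
        return out


@dataclass
class GrowthSimulation:
    """One simulated plot: measured-equivalent data plus the ground truth."""

    stand: StandInventory                 # final inventory (observed DBHs)
    rings: dict[str, RingSeries]          # tree-level widths, ALL trees
    true_ci: pd.DataFrame                 # years × tree, end-of-year Hegyi CI
    z: pd.Series                          # growing-season moisture z-score

    def cored_rings(self) -> dict[str, RingSeries]:
        cored = set(self.stand.trees.loc[self.stand.trees["cored"].astype(bool),
                                         "tree_id"])
        return {t: r for t, r in self.rings.items() if t in cored}


@dataclass
class SiteSimulation:
    """A site: one shared climate, several plots at different densities."""

    climate: ClimateSeries
    plots: list[GrowthSimulation]
    configs: list[SimulationConfig]
    site_index: dict[str, float]          # plot_id -> dominant height at age 40


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------

_MONTHS = np.arange(1, 13)


def _monthly_precip_fractions() -> np.ndarray:
    raw = 0.30 + 2.4 * np.exp(-((_MONTHS - 7.5) ** 2) / (2 * 1.8**2))
    return raw / raw.sum()


def gen_climate(config: SimulationConfig) -> ClimateSeries:
    """Generate a monthly climate record covering the stand's lifetime.

    The record starts ``climate_spinup_years`` before planting (so lagged
    climate windows and SPEI fits have support) and ends with the last
    growth year. Temperature is a seasonal sinusoid plus optional linear
    trend and Gaussian noise; monthly precipitation is gamma-distributed
    around a July–August-peaked seasonal mean; RH is a noisy sinusoid
    clipped to (0, 100]. Imposed droughts scale April–October precipitation
    of the affected years by ``exp(−severity)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 11)))
    y0 = config.planting_year - config.climate_spinup_years
    y1 = config.planting_year + config.n_years - 1
    years = np.repeat(np.arange(y0, y1 + 1), 12)
    months = np.tile(_MONTHS, y1 - y0 + 1)
    n = len(years)

    t_season = config.t_base + config.t_amp * np.cos(2 * np.pi * (months - 7) / 12.0)
    t = (t_season + config.t_trend * (years - y0)
         + rng.normal(0.0, config.t_noise_sd, n))

    frac = _monthly_precip_fractions()
    p_mean = config.p_annual_mm * frac[months - 1]
    scale = p_mean / config.p_shape
    p = rng.gamma(config.p_shape, scale, n)

    drought = config.imposed_drought_years()
    if drought:
        hit = np.isin(years, list(drought)) & (months >= 4) & (months <= 10)
        severities = {}
        for start, duration, sev in config.drought_years:
            for y in range(start, start + duration):
                severities[y] = sev
        factors = np.array([math.exp(-severities.get(y, 0.0)) for y in years])
        p = np.where(hit, p * factors, p)

    rh = (config.rh_base + config.rh_amp * np.cos(2 * np.pi * (months - 7.5) / 12.0)
          + rng.normal(0.0, config.rh_noise_sd, n))
    rh = np.clip(rh, 5.0, 100.0)

    df = pd.DataFrame({"year": years, "month": months, "tmean_c": t,
                       "prcp_mm": p, "rh_pct": rh})
    return ClimateSeries(df, latitude=config.latitude)


# ---------------------------------------------------------------------------
# stand
# ---------------------------------------------------------------------------

def gen_stand(config: SimulationConfig) -> StandInventory:
    """Place trees on a jittered lattice inside the plot rectangle.

    ``⌊plot area × density⌋`` trees are assigned to distinct lattice cells
    and jittered within the central 80% of their cell, which guarantees all
    pairwise distances are strictly positive. All trees share the planting
    year; a ``cored_fraction`` of them (at least 3) is flagged as cored.
    DBH is initialized at the seedling caliper and is filled in by
    :func:`gen_growth`.
    """
    n = config.resolved_n_trees()
    if n < 2:
        raise ValueError("density infeasible: fewer than 2 trees on the plot")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 23)))

    ncell = int(math.ceil(math.sqrt(n)))
    cells = [(i, j) for i in range(ncell) for j in range(ncell)]
    order = rng.permutation(len(cells))[:n]
    cw = config.plot_width / ncell
    ch = config.plot_height / ncell
    xs, ys = [], []
    for k in order:
        i, j = cells[k]
        xs.append((i + 0.1 + 0.8 * rng.random()) * cw)
        ys.append((j + 0.1 + 0.8 * rng.random()) * ch)

    n_cored = max(3, int(round(config.cored_fraction * n)))
    cored = np.zeros(n, dtype=bool)
    cored[rng.choice(n, size=min(n_cored, n), replace=False)] = True

    trees = pd.DataFrame({
        "tree_id": [f"t{k + 1:03d}" for k in range(n)],
        "x_m": xs,
        "y_m": ys,
        "dbh_cm": INITIAL_DIAMETER_CM,
        "height_m": 0.3,
        "cored": cored,
    })
    plot_id = f"sim-d{int(config.density) if config.density else n}"
    return StandInventory(plot_id=plot_id, width_m=config.plot_width,
                          height_m=config.plot_height,
                          planting_year=config.planting_year, trees=trees)


def _allometric_height(dbh_cm: np.ndarray) -> np.ndarray:
    """Total height (m) from DBH; saturating curve for a mid-sized pine."""
    return 1.3 + 22.0 * (1.0 - np.exp(-0.045 * np.asarray(dbh_cm))) ** 1.1


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

def growing_season_z(climate: ClimateSeries, years: np.ndarray) -> pd.Series:
    """Z-score of the April–October climatic balance, own-record climatology."""
    from .climate import climatic_balance
    d = climatic_balance(climate)
    df = climate.data
    mask = (df["month"] >= 4) & (df["month"] <= 10)
    sums = pd.Series(d[mask.to_numpy()], index=df.loc[mask, "year"].to_numpy())
    annual = sums.groupby(level=0).sum()
    z = (annual - annual.mean()) / annual.std(ddof=1)
    return z.reindex(years)


def gen_growth(stand: StandInventory, climate: ClimateSeries,
               config: SimulationConfig) -> GrowthSimulation:
    """Simulate ring widths and the true annual competition trajectory.

    Widths follow the multiplicative model in the module docstring; the
    Hegyi CI entering year t's growth is computed from the diameters at the
    start of that year, while the recorded ``true_ci`` holds end-of-year
    values (the quantity the retroactive reconstruction estimates). The
    drought-legacy penalty is keyed to the realized growing-season moisture
    z-score (z < ``legacy_trigger_z``), so imposed and naturally occurring
    severe droughts alike depress post-drought growth of crowded trees.
    """
    years = config.years
    z = growing_season_z(climate, years)
    if z.isna().any():
        raise ValueError("climate does not cover the stand lifetime")

    n = len(stand)
    dist = stand.distance_matrix()
    dbh = np.full(n, INITIAL_DIAMETER_CM)

    # drought legacy follows the *realized* growing-season moisture: the
    # legacy_years AFTER a severe-drought year (z below the trigger) carry
    # the competition-dependent penalty. The drought year itself is only
    # depressed through the climate term, so resistance stays density-
    # independent while recovery and (relative) resilience do not.
    severe = [int(y) for y in years if z.loc[y] < config.legacy_trigger_z]
    legacy: set[int] = set()
    for y in severe:
        legacy.update(range(y + 1, y + config.legacy_years + 1))

    tree_ss = np.random.SeedSequence((config.seed, 37)).spawn(n)
    noise = np.stack([np.random.default_rng(s).normal(0.0, config.sigma_noise,
                                                      len(years))
                      for s in tree_ss])  # (n, n_years); 0 when sigma is 0

    ages = np.arange(1, config.n_years + 1)
    age_trend = (config.width_asymptote
                 + (config.width_young - config.width_asymptote)
                 * np.exp(-(ages - 1) / config.age_tau))

    widths = np.empty((n, len(years)))
    ci_end = np.empty((n, len(years)))
    for t, year in enumerate(years):
        ci_now = _ci_matrix(dbh, dist, radius=8.0)
        lam = config.drought_legacy if year in legacy else 0.0
        log_w = (np.log(age_trend[t])
                 + config.beta_climate * z.loc[year]
                 - config.gamma_competition * ci_now
                 - lam * ci_now
                 + noise[:, t])
        w = np.exp(log_w)
        widths[:, t] = w
        dbh = dbh + 2.0 * w / 10.0
        ci_end[:, t] = _ci_matrix(dbh, dist, radius=8.0)

    trees = stand.trees.copy()
    trees["dbh_cm"] = dbh
    trees["height_m"] = _allometric_height(dbh)
    final = StandInventory(plot_id=stand.plot_id, width_m=stand.width_m,
                           height_m=stand.height_m,
                           planting_year=stand.planting_year, trees=trees)

    rings = {}
    for k, tid in enumerate(trees["tree_id"]):
        rings[tid] = RingSeries(core_id=f"{tid}a", tree_id=tid,
                                plot_id=stand.plot_id,
                                first_year=int(years[0]), widths=widths[k])
    true_ci = pd.DataFrame(ci_end.T, index=years, columns=trees["tree_id"])
    return GrowthSimulation(stand=final, rings=rings, true_ci=true_ci, z=z)


def simulate_plot(config: SimulationConfig,
                  climate: ClimateSeries | None = None) -> GrowthSimulation:
    """Convenience: stand + climate + growth from one configuration."""
    if climate is None:
        climate = gen_climate(config)
    return gen_growth(gen_stand(config), climate, config)


def site_index_from_stand(sim: GrowthSimulation, base_age: int = 40,
                          k: float = 0.08, c: float = 1.2) -> float:
    """Dominant height at the base age via a Richards height-age curve.

    Dominant height = mean height of the three largest-DBH trees at the
    final simulated age, projected to ``base_age`` along
    H(a) = 1.3 + A·(1 − exp(−k·a))^c.
    """
    trees = sim.stand.trees.nlargest(3, "dbh_cm")
    h_dom = float(trees["height_m"].mean())
    age = len(sim.true_ci)
    scale = ((1.0 - math.exp(-k * base_age)) ** c
             / (1.0 - math.exp(-k * age)) ** c)
    return 1.3 + (h_dom - 1.3) * scale


def simulate_site(config: SimulationConfig,
                  densities: tuple = (250.0, 550.0, 900.0)) -> SiteSimulation:
    """Simulate one site: a shared climate and one plot per density class.

    The density triple mirrors the low/medium/high stocking contrast of the
    study design. Each plot gets its own seed stream derived from the base
    seed and its position in ``densities``, so plots are independent but the
    whole site is reproducible.
    """
    climate = gen_climate(config)
    plots, configs = [], []
    site_index = {}
    for k, d in enumerate(densities):
        cfg = replace(config, density=float(d), n_trees=None,
                      seed=config.seed * 1000 + 101 * (k + 1))
        stand = gen_stand(cfg)
        # site-unique identifiers so plots can be pooled in one table
        prefix = f"p{k + 1}"
        stand.trees["tree_id"] = prefix + stand.trees["tree_id"]
        sim = gen_growth(stand, climate, cfg)
        plot_id = f"plot-{k + 1}-d{int(d)}"
        sim.stand.plot_id = plot_id
        for r in sim.rings.values():
            r.plot_id = plot_id
        plots.append(sim)
        configs.append(cfg)
        site_index[sim.stand.plot_id] = site_index_from_stand(sim)
    return SiteSimulation(climate=climate, plots=plots, configs=configs,
                          site_index=site_index)
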