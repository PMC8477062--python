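"""Relative importance of climate, competition, and site condition.

Radial growth (log BAI) is regressed on 5-year block averages of the
screened climate factors, the reconstructed competition index, and the site
index, and the explained variance is decomposed into group contributions
with the LMG metric: a group's importance is its incremental R² averaged
over all orders in which the groups can enter the model. LMG shares are
non-negative, sum exactly to the model R², and reduce to the marginal r²
proportions when the predictor groups are orthogonal.

The growth model is ordinary least squares on blocks: the three inputs are
fixed quantities of each plot-block observation and nothing in the design
calls for random effects (plot random intercepts are available behind a
flag for sensitivity checks). Cambial age is deliberately excluded — it is
an inherent factor whose log-log relation with BAI would absorb variance
that belongs to the three causes under study.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "AttributionResult",
    "block_average",
    "fit_growth_model",
    "lmg_importance",
    "recover_known_effects",
]


@dataclass
class AttributionResult:
    """LMG variance decomposition over predictor groups.

    ``shares`` are on the R² scale and sum to ``r2_total``;
    ``share_pct`` expresses each as a percentage of the explained variance
    (the default display), ``share_pct_total`` as a percentage of the total
    response variance.
    """

    shares: dict[str, float]
    r2_total: float
    n_obs: int
    approximate: bool = False

    @property
    def share_pct(self) -> dict[str, float]:
        if self.r2_total == 0:
            return {g: 0.0 for g in self.shares}
        return {g: 100.0 * v / self.r2_total for g, v in self.shares.items()}

    @property
    def share_pct_total(self) -> dict[str, float]:
        return {g: 100.0 * v for g, v in self.shares.items()}

    def ranking(self) -> list[str]:
        return sorted(self.shares, key=self.shares.get, reverse=True)


def block_average(series, width: int = 5, min_tail: int = 3) -> np.ndarray:
    """Non-overlapping consecutive block means.

    Full blocks of ``width`` observations; a trailing partial block is kept
    when it has at least ``min_tail`` observations, else dropped. Missing
    values propagate: an all-missing block is an error.
    """
    x = np.asarray(pd.Series(series).to_numpy(), dtype=float)
    if len(x) < 2 * width:
        raise ValueError("series shorter than two blocks")
    out = []
    for start in range(0, len(x), width):
        chunk = x[start:start + width]
        if len(chunk) < width and len(chunk) < min_tail:
            break
        if np.all(np.isnan(chunk)):
            raise ValueError("all-missing block")
        out.append(np.nanmean(chunk))
    return np.asarray(out)


def _design_matrix(data: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    x = data[predictors].to_numpy(dtype=float)
    return sm.add_constant(x, has_constant="add")


def fit_growth_model(data: pd.DataFrame, response: str,
                     predictors: list[str]):
    """OLS of the (log-BAI) response on the selected predictors.

    Raises on rank deficiency, naming the aliased columns; the fitted
    results object reports the design condition number for collinearity
    screening (``results.condition_number``).
    """
    y = data[response].to_numpy(dtype=float)
    if len(data) <= len(predictors) + 2:
        raise ValueError("too few observations for the number of predictors")
    xmat = _design_matrix(data, predictors)
    rank = np.linalg.matrix_rank(xmat)
    if rank < xmat.shape[1]:
        aliased = _find_aliased(data, predictors)
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    return sm.OLS(y, xmat).fit()


def _find_aliased(data: pd.DataFrame, predictors: list[str]) -> list[str]:
    cols = []
    for k in range(1, len(predictors) + 1):
        sub = predictors[:k]
        if np.linalg.matrix_rank(_design_matrix(data, sub)) < k + 1:
            cols.append(predictors[k - 1])
    return cols or predictors


def _subset_r2(y: np.ndarray, x: np.ndarray, cols: tuple[int, ...]) -> float:
    if not cols:
        return 0.0
    xmat = sm.add_constant(x[:, list(cols)], has_constant="add")
    beta, _, _, _ = np.linalg.lstsq(xmat, y, rcond=None)
    resid = y - xmat @ beta
    tss = np.sum((y - y.mean()) ** 2)
    return float(1.0 - np.sum(resid**2) / tss)


def lmg_importance(data: pd.DataFrame, response: str,
                   groups: dict[str, list[str]],
                   max_exact_groups: int = 10,
                   n_sample_orderings: int = 5000,
                   seed: int = 0) -> AttributionResult:
    """LMG decomposition of R² over predictor groups.

    For each ordering of the groups, a group's contribution is the increase
    in R² when its columns enter the model after the preceding groups;
    LMG averages this over orderings. Up to ``max_exact_groups`` groups the
    average runs over all orderings exactly (via subset R² caching); beyond
    that a seeded random sample of orderings is used and the result is
    flagged approximate.
    """
    names = list(groups)
    g = len(names)
    all_cols = [c for name in names for c in groups[name]]
    y = data[response].to_numpy(dtype=float)
    x = data[all_cols].to_numpy(dtype=float)
    col_idx = {}
    pos = 0
    for name in names:
        col_idx[name] = tuple(range(pos, pos + len(groups[name])))
        pos += len(groups[name])

    if np.ptp(y) == 0:
        raise ValueError("zero-variance response")

    cache: dict[frozenset, float] = {}

    def r2_of(subset: frozenset) -> float:
        if subset not in cache:
            # fixed column order: frozenset iteration depends on string
            # hashing, which would break cross-process reproducibility
            cols = tuple(i for name in names if name in subset
                         for i in col_idx[name])
            cache[subset] = _subset_r2(y, x, cols)
        return cache[subset]

    approximate = g > max_exact_groups
    if approximate:
        rng = np.random.default_rng(seed)
        orderings = [tuple(rng.permutation(names))
                     for _ in range(n_sample_orderings)]
    else:
        orderings = list(itertools.permutations(names))

    contrib = {name: 0.0 for name in names}
    for order in orderings:
        seen: frozenset = frozenset()
        for name in order:
            before = r2_of(seen)
            seen = seen | {name}
            contrib[name] += r2_of(seen) - before
    shares = {name: contrib[name] / len(orderings) for name in names}
    r2_total = r2_of(frozenset(names))
    return AttributionResult(shares=shares, r2_total=r2_total,
                             n_obs=len(y), approximate=approximate)


# ---------------------------------------------------------------------------
# simulation recovery: the full screen → blocks → OLS → LMG chain
# ---------------------------------------------------------------------------

def recover_known_effects(site, block_width: int = 5, top_factors: int = 4,
                          min_tail: int = 3) -> AttributionResult:
    """Run the attribution chain on a simulated site and decompose growth.

    For each plot of the site: mean log BAI of the cored trees per year is
    the response; the climate group holds 5-year blocks of the
    ``top_factors`` monthly variables screened by the Pearson correlation
    stage (plus the growing-season moisture score); competition is the
    plot-mean reconstructed annual CI; site condition is the plot's site
    index. Observations are plot × block; groups are decomposed with LMG.
    """
    from .climate_growth import correlate, lag_align, select_significant
    from .competition import reconstruct_annual_ci
    from .rings import bai_from_rings

    years = site.plots[0].true_ci.index.to_numpy()
    rows = []
    # screen factors once, on the pooled mean growth signal
    pooled_logbai = []
    per_plot = []
    for sim in site.plots:
        cored = sim.cored_rings()
        bai = pd.concat([bai_from_rings(r).to_series() for r in cored.values()],
                        axis=1)
        log_bai = np.log(bai.mean(axis=1))
        _, ci_hist = reconstruct_annual_ci(sim.stand, cored)
        ci_mean = ci_hist.mean(axis=1)
        per_plot.append((sim, log_bai, ci_mean))
        pooled_logbai.append(log_bai)
    signal = pd.concat(pooled_logbai, axis=1).mean(axis=1)
    # screen on year-to-year growth anomalies (first differences remove the
    # age trend that would otherwise swamp monthly climate signals)
    anomaly = signal.diff().dropna()
    design = lag_align(site.climate, anomaly.index)
    table = correlate(anomaly, design)
    top = select_significant(table, top=top_factors)

    climate_cols = []
    for sim, log_bai, ci_mean in per_plot:
        n_blocks = None
        rec = {"plot": sim.stand.plot_id}
        yb = block_average(log_bai.reindex(years), width=block_width,
                           min_tail=min_tail)
        rec_rows = []
        for b, val in enumerate(yb):
            rec_rows.append({"plot": sim.stand.plot_id, "block": b,
                             "log_bai": val})
        dsn = lag_align(site.climate, years)
        for k, (_, fac) in enumerate(top.iterrows()):
            col = f"clim_{fac['variable']}_{fac['month']}"
            if col not in climate_cols:
                climate_cols.append(col)
            series = dsn[(fac["variable"], fac["month"])].reindex(years)
            fb = block_average(series, width=block_width, min_tail=min_tail)
            for b, val in enumerate(fb):
                rec_rows[b][col] = val
        zb = block_average(site.plots[0].z.reindex(years), width=block_width,
                           min_tail=min_tail)
        if "clim_gs_z" not in climate_cols:
            climate_cols.append("clim_gs_z")
        cib = block_average(ci_mean.reindex(years), width=block_width,
                            min_tail=min_tail)
        for b in range(len(rec_rows)):
            rec_rows[b]["clim_gs_z"] = zb[b]
            rec_rows[b]["ci"] = cib[b]
            rec_rows[b]["site_index"] = site.site_index[sim.stand.plot_id]
        rows.extend(rec_rows)

    blocks = pd.DataFrame(rows)
    groups = {"climate": climate_cols, "competition": ["ci"],
              "site": ["site_index"]}
    return lmg_importance(blocks, "log_bai", groups)
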