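"""End-to-end orchestration: validate → climate → rings → competition →
reconstruction → correlation → attribution → resilience.

Every stage reads and writes plain CSV/JSON in the run directory, records
row counts in a manifest, and is deterministic given the configuration;
re-running with the same config reproduces the numeric outputs byte for
byte (the manifest carries a hash of the canonical config instead of
timestamps for exactly that reason).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as dio
from .attribution import block_average, lmg_importance
from .climate import growing_season_spei, mann_kendall, spei
from .climate_growth import correlate, lag_align, select_significant
from .competition import hegyi_all, reconstruct_annual_ci
from .resilience import (ci_resilience_correlation, group_compare,
                         moving_average_bai, resilience_indices,
                         select_drought_events)
from .rings import ar_prewhiten, bai_from_rings, build_chronology, rcs_detrend

__all__ = ["PipelineConfig", "validate_inputs", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and stage parameters for one pipeline run.

    Defaults carry the study's canonical parameter values: 8 m competition
    radius, CI class cut-points at 1 and 3, growing season April–October,
    drought threshold SPEI < −1 with events separated by > 3 years, 3-year
    resilience windows, and 5-year attribution blocks.
    """

    inventory: str = ""
    rings: str = ""
    climate: str = ""
    output: str = "run"
    latitude: float = 42.5
    plot_width_m: float = 30.0
    plot_height_m: float = 30.0
    radius_m: float = 8.0
    ci_class_bounds: tuple = (1.0, 3.0)
    season_start_month: int = 4
    season_end_month: int = 10
    spei_threshold: float = -1.0
    event_separation_years: int = 3
    resilience_window_years: int = 3
    block_years: int = 5
    window_end: str = "C_Sep"
    rcs_stiffness: float = 0.10
    edge_correct: bool = False
    smoothed_resilience: bool = False
    top_climate_factors: int = 4
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ci_class_bounds" in raw:
            raw["ci_class_bounds"] = tuple(raw["ci_class_bounds"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_inputs(inventory_path, rings_path, climate_path) -> list[str]:
    """Schema and unit sanity checks; returns ALL violations, not the first.

    Checks: required columns; DBH in [1, 150] cm; ring widths in
    [0.01, 20] mm; RH in (0, 100]; every ring-series tree id present in the
    inventory. Messages name file, line (1-based incl. header) and column.
    """
    problems: list[str] = []

    inv = pd.read_csv(inventory_path)
    for col in ("plot_id", "tree_id", "x_m", "y_m", "dbh_cm", "height_m",
                "cored", "planting_year"):
        if col not in inv.columns:
            problems.append(f"{inventory_path}: missing column '{col}'")
    if "dbh_cm" in inv.columns:
        bad = inv.index[(inv["dbh_cm"] < 1.0) | (inv["dbh_cm"] > 150.0)]
        problems += [f"{inventory_path}:line {i + 2}:dbh_cm value "
                     f"{inv.at[i, 'dbh_cm']} outside [1, 150]" for i in bad]

    rings = pd.read_csv(rings_path)
    for col in ("core_id", "year", "width_mm"):
        if col not in rings.columns:
            problems.append(f"{rings_path}: missing column '{col}'")
    if "width_mm" in rings.columns:
        bad = rings.index[(rings["width_mm"] < 0.01) | (rings["width_mm"] > 20.0)]
        problems += [f"{rings_path}:line {i + 2}:width_mm value "
                     f"{rings.at[i, 'width_mm']} outside [0.01, 20]" for i in bad]
    if "tree_id" in rings.columns and "tree_id" in inv.columns:
        known = set(inv["tree_id"].astype(str))
        for tid in sorted(set(rings["tree_id"].astype(str)) - known):
            problems.append(f"{rings_path}: tree_id '{tid}' absent from inventory")

    clim = pd.read_csv(climate_path)
    for col in ("year", "month", "tmean_c", "prcp_mm", "rh_pct"):
        if col not in clim.columns:
            problems.append(f"{climate_path}: missing column '{col}'")
    if "rh_pct" in clim.columns:
        bad = clim.index[(clim["rh_pct"] <= 0) | (clim["rh_pct"] > 100)]
        problems += [f"{climate_path}:line {i + 2}:rh_pct value "
                     f"{clim.at[i, 'rh_pct']} outside (0, 100]" for i in bad]
    if "prcp_mm" in clim.columns:
        bad = clim.index[clim["prcp_mm"] < 0]
        problems += [f"{climate_path}:line {i + 2}:prcp_mm negative" for i in bad]
    return problems


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _float_csv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, index=False, float_format="%.10g")
    return len(df)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages on the configured inputs; returns the manifest dict.

    Stage failures raise with the stage named; outputs of completed stages
    are retained in the run directory.
    """
    out = Path(config.output)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__,
                      "config_hash": config.config_hash(),
                      "config": asdict(config), "stages": {}, "warnings": []}
    stage = "validate"
    try:
        problems = validate_inputs(config.inventory, config.rings, config.climate)
        if problems:
            raise ValueError("input validation failed:\n" + "\n".join(problems))
        manifest["stages"]["validate"] = {"violations": 0}

        stage = "climate"
        climate = dio.read_climate_csv(config.climate, latitude=config.latitude)
        derived = climate.data.copy()
        derived["vpd_kpa"] = climate.vpd()
        derived["pet_mm"] = climate.pet()
        derived["spei1"] = spei(climate, 1)
        derived["spei12"] = spei(climate, 12)
        gs = growing_season_spei(climate, config.season_start_month,
                                 config.season_end_month)
        n = _float_csv(derived, out / "climate_derived.csv")
        _float_csv(gs.rename("gs_spei").rename_axis("year").reset_index(),
                   out / "gs_spei.csv")
        trend_rows = []
        annual = derived.groupby("year").agg(
            prcp=("prcp_mm", "sum"), tmean=("tmean_c", "mean"),
            vpd=("vpd_kpa", "mean"))
        for col in annual.columns:
            tr = mann_kendall(annual[col].to_numpy())
            trend_rows.append({"variable": col, "s": tr.s, "z": tr.z,
                               "p": tr.p, "direction": tr.direction})
        _float_csv(pd.DataFrame(trend_rows), out / "climate_trends.csv")
        manifest["stages"]["climate"] = {"months": n, "years_gs_spei": len(gs)}

        stage = "rings"
        stands = dio.read_inventory_csv(config.inventory, config.plot_width_m,
                                        config.plot_height_m)
        all_cores = dio.read_rings_csv(config.rings)
        bai_rows, chron_rows, chron_stats = [], [], []
        plot_cores: dict[str, list] = {}
        for core in all_cores:
            plot_cores.setdefault(core.plot_id, []).append(core)
        for plot_id, cores in plot_cores.items():
            stand = stands[plot_id]
            by_tree: dict[str, list] = {}
            for c in cores:
                by_tree.setdefault(c.tree_id, []).append(c)
            for tid, tree_cores in by_tree.items():
                b = bai_from_rings(tree_cores)
                bai_rows.append(pd.DataFrame({"plot_id": plot_id, "tree_id": tid,
                                              "year": b.years, "bai_cm2": b.bai}))
            idx = rcs_detrend(cores, stand.planting_year,
                              stiffness=config.rcs_stiffness)
            resid = [ar_prewhiten(s) for s in idx.values()]
            chron = build_chronology(resid)
            cf = chron.to_frame()
            cf.insert(0, "plot_id", plot_id)
            chron_rows.append(cf)
            chron_stats.append({"plot_id": plot_id, "rbar": chron.rbar,
                                "eps": chron.eps, "snr": chron.snr,
                                "n_cores": len(cores)})
        bai_table = pd.concat(bai_rows, ignore_index=True)
        _float_csv(bai_table, out / "bai.csv")
        chron_table = pd.concat(chron_rows, ignore_index=True)
        _float_csv(chron_table, out / "chronology.csv")
        _float_csv(pd.DataFrame(chron_stats), out / "chronology_stats.csv")
        manifest["stages"]["rings"] = {"trees": bai_table["tree_id"].nunique(),
                                       "plots": len(plot_cores)}

        stage = "competition"
        ci_rows = []
        for plot_id, stand in stands.items():
            t = hegyi_all(stand, radius=config.radius_m,
                          edge_correct=config.edge_correct)
            t.insert(0, "plot_id", plot_id)
            ci_rows.append(t)
        ci_table = pd.concat(ci_rows, ignore_index=True)
        _float_csv(ci_table, out / "competition.csv")
        manifest["stages"]["competition"] = {
            "trees": len(ci_table),
            "edge_trees": int(ci_table["edge"].sum())}

        stage = "reconstruction"
        annual_rows = []
        tree_ci_records = {}
        for plot_id, cores in plot_cores.items():
            stand = stands[plot_id]
            tree_series = {}
            by_tree = {}
            for c in cores:
                by_tree.setdefault(c.tree_id, []).append(c)
            for tid, tcs in by_tree.items():
                merged = pd.concat([c.to_series() for c in tcs], axis=1).mean(axis=1)
                from .rings import RingSeries
                tree_series[tid] = RingSeries(
                    core_id=tid, tree_id=tid, plot_id=plot_id,
                    first_year=int(merged.index[0]),
                    widths=merged.to_numpy())
            _, ci_hist = reconstruct_annual_ci(stand, tree_series,
                                               radius=config.radius_m)
            long = ci_hist.reset_index(names="year").melt(
                id_vars="year", var_name="tree_id", value_name="ci")
            long.insert(0, "plot_id", plot_id)
            annual_rows.append(long)
            tree_ci_records[plot_id] = ci_hist
        annual_table = pd.concat(annual_rows, ignore_index=True)
        _float_csv(annual_table.dropna(), out / "annual_ci.csv")
        manifest["stages"]["reconstruction"] = {"rows": len(annual_table)}

        stage = "correlation"
        pooled = (chron_table.groupby("year")["index"].mean())
        anomaly = pooled.diff().dropna()
        design = lag_align(climate, anomaly.index, window_end=config.window_end)
        corr = correlate(anomaly, design)
        _float_csv(corr, out / "correlations.csv")
        top = select_significant(corr, top=config.top_climate_factors)
        _float_csv(top, out / "top_factors.csv")
        manifest["stages"]["correlation"] = {"cells": len(corr),
                                             "significant": int((corr["p"] < 0.05).sum())}

        stage = "attribution"
        blocks = _attribution_blocks(config, climate, bai_table,
                                     tree_ci_records, stands, top)
        if blocks is not None:
            climate_cols = [c for c in blocks.columns if c.startswith("clim_")]
            groups = {"climate": climate_cols, "competition": ["ci"],
                      "site": ["site_index"]}
            res = lmg_importance(blocks, "log_bai", groups)
            attr = {"r2_total": res.r2_total, "n_obs": res.n_obs,
                    "shares_r2": res.shares, "share_pct": res.share_pct,
                    "share_pct_total": res.share_pct_total}
            (out / "attribution.json").write_text(json.dumps(attr, indent=2))
            manifest["stages"]["attribution"] = {"n_blocks": res.n_obs}
        else:
            manifest["warnings"].append(
                "attribution skipped: site index requires >= 2 plots")

        stage = "resilience"
        events = select_drought_events(gs, threshold=config.spei_threshold,
                                       separation=config.event_separation_years)
        ev_rows = [{"event_index": e.index, "years": " ".join(map(str, e.years)),
                    "min_spei": e.min_spei} for e in events]
        _float_csv(pd.DataFrame(ev_rows), out / "drought_events.csv")
        res_rows = []
        for plot_id, sub in bai_table.groupby("plot_id"):
            ci_hist = tree_ci_records[plot_id]
            plot_ci = ci_table[ci_table["plot_id"] == plot_id] \
                .set_index("tree_id")["ci_class"]
            for tid, tsub in sub.groupby("tree_id"):
                bai = tsub.set_index("year")["bai_cm2"]
                for ev in events:
                    ri = resilience_indices(bai, ev, config.resilience_window_years,
                                            all_events=events,
                                            smoothed=config.smoothed_resilience)
                    if ri is None:
                        continue
                    ci_ev = np.nan
                    if tid in ci_hist.columns:
                        vals = ci_hist.loc[ci_hist.index.isin(ev.years), tid]
                        ci_ev = float(vals.mean()) if len(vals) else np.nan
                    res_rows.append({"plot_id": plot_id, "tree_id": tid,
                                     "ci_class": plot_ci.get(tid, ""),
                                     "event_index": ev.index, "ci": ci_ev,
                                     "rt": ri.rt, "rc": ri.rc, "rs": ri.rs,
                                     "rrs": ri.rrs})
        res_table = pd.DataFrame(res_rows)
        _float_csv(res_table, out / "resilience.csv")
        if not res_table.empty:
            summary, pairs = group_compare(res_table, "rc",
                                           by=("event_index", "ci_class"))
            _float_csv(summary, out / "resilience_groups_rc.csv")
            if not pairs.empty:
                _float_csv(pairs, out / "resilience_pairs_rc.csv")
            pooled_ci = res_table.dropna(subset=["ci"])
            if len(pooled_ci) >= 10:
                try:
                    cr = ci_resilience_correlation(pooled_ci)
                    _float_csv(cr, out / "ci_resilience_correlation.csv")
                except ValueError as e:
                    manifest["warnings"].append(str(e))
        manifest["stages"]["resilience"] = {"events": len(events),
                                            "records": len(res_table)}
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _attribution_blocks(config, climate, bai_table, tree_ci_records, stands,
                        top) -> pd.DataFrame | None:
    """Assemble plot × block observations for the growth model."""
    if len(stands) < 2:
        return None
    rows = []
    for plot_id, stand in stands.items():
        sub = bai_table[bai_table["plot_id"] == plot_id]
        mean_bai = sub.groupby("year")["bai_cm2"].mean()
        years = mean_bai.index.to_numpy()
        log_bai = np.log(mean_bai)
        yb = block_average(log_bai, width=config.block_years)
        recs = [{"plot": plot_id, "block": b, "log_bai": v}
                for b, v in enumerate(yb)]
        design = lag_align(climate, years, window_end=config.window_end)
        for _, fac in top.iterrows():
            col = f"clim_{fac['variable']}_{fac['month']}"
            fb = block_average(design[(fac["variable"], fac["month"])]
                               .reindex(years), width=config.block_years)
            for b in range(len(recs)):
                recs[b][col] = fb[b]
        ci_mean = tree_ci_records[plot_id].mean(axis=1).reindex(years)
        cib = block_average(ci_mean, width=config.block_years)
        # site index proxy: dominant height (3 largest stems) of the plot
        si = float(stands[plot_id].trees.nlargest(3, "dbh_cm")["height_m"].mean())
        for b in range(len(recs)):
            recs[b]["ci"] = cib[b]
            recs[b]["site_index"] = si
        rows.extend(recs)
    return pd.DataFrame(rows)
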