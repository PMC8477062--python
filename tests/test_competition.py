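"""Hegyi index, CI classes, growth rates, and the retroactive reconstruction."""

import numpy as np
import pandas as pd
import pytest

import dendrocomp as dc
from dendrocomp.competition import (StandInventory, annual_ci, backcast_dbh,
                                    classify_ci, growth_rate_series, hegyi_all,
                                    hegyi_ci, plot_growth_rate,
                                    reconstruct_annual_ci)
from dendrocomp.rings import RingSeries

from conftest import brute_force_hegyi


def _stand(rows, w=30.0, h=30.0):
    trees = pd.DataFrame(rows, columns=["tree_id", "x_m", "y_m", "dbh_cm"])
    trees["height_m"] = 10.0
    trees["cored"] = False
    return StandInventory(plot_id="x", width_m=w, height_m=h,
                          planting_year=1980, trees=trees)


# ---------------------------------------------------------------------------
# Hegyi CI
# ---------------------------------------------------------------------------

def test_hegyi_single_equal_competitor_at_1m():
    s = _stand([("a", 10, 10, 20.0), ("b", 11, 10, 20.0)])
    assert hegyi_ci(s, "a").ci == pytest.approx(1.0)


def test_hegyi_double_dbh_at_2m():
    s = _stand([("a", 10, 10, 20.0), ("b", 12, 10, 40.0)])
    assert hegyi_ci(s, "a").ci == pytest.approx(1.0)  # 2 * (1/2)


def test_hegyi_outside_radius_excluded():
    s = _stand([("a", 10, 10, 20.0), ("b", 20, 10, 20.0)])
    r = hegyi_ci(s, "a", radius=8.0)
    assert r.ci == 0.0 and r.n_competitors == 0


def test_hegyi_random_stands_match_bruteforce():
    rng = np.random.default_rng(0)
    for _ in range(25):
        n = rng.integers(5, 60)
        rows = [(f"t{i}", rng.uniform(0, 30), rng.uniform(0, 30),
                 rng.uniform(5, 40)) for i in range(n)]
        s = _stand(rows)
        got = hegyi_all(s).set_index("tree_id")["ci"]
        want = brute_force_hegyi(s)
        for tid, ci in want.items():
            assert got[tid] == pytest.approx(ci, abs=1e-12)


def test_hegyi_coincident_positions_rejected():
    s = _stand([("a", 10, 10, 20.0), ("b", 10, 10, 20.0)])
    with pytest.raises(ValueError, match="coincident"):
        hegyi_all(s)


def test_hegyi_radius_monotonicity():
    rng = np.random.default_rng(1)
    rows = [(f"t{i}", rng.uniform(0, 30), rng.uniform(0, 30),
             rng.uniform(5, 40)) for i in range(40)]
    s = _stand(rows)
    ci8 = hegyi_all(s, radius=8.0)["ci"].to_numpy()
    ci5 = hegyi_all(s, radius=5.0)["ci"].to_numpy()
    assert np.all(ci5 <= ci8 + 1e-12)


def test_edge_correction_never_negative_and_flags_edges():
    rng = np.random.default_rng(2)
    rows = [(f"t{i}", rng.uniform(0, 30), rng.uniform(0, 30),
             rng.uniform(5, 40)) for i in range(40)]
    t = hegyi_all(_stand(rows), edge_correct=True)
    assert (t["ci"] >= 0).all()
    assert t["edge"].any()  # 8 m disc cannot fit everywhere in a 30 m plot


@pytest.mark.parametrize("ci, cls", [
    (0.37, "low"),    # typical low-density stand mean
    (0.99, "low"),
    (1.0, "medium"),  # boundary: half-open intervals
    (2.99, "medium"),
    (3.0, "high"),
    (4.18, "high"),   # typical high-density stand mean
])
def test_classify_ci(ci, cls):
    assert classify_ci(ci) == cls


def test_classify_ci_rejects_negative():
    with pytest.raises(ValueError):
        classify_ci(-0.1)


# ---------------------------------------------------------------------------
# growth rates
# ---------------------------------------------------------------------------

def _core(widths, first_year=1980, tree_id="t1"):
    return RingSeries(core_id=tree_id + "a", tree_id=tree_id, plot_id="x",
                      first_year=first_year, widths=np.asarray(widths, float))


def test_growth_rate_uniform():
    gr = growth_rate_series(_core([1, 1, 1, 1]))
    assert np.allclose(gr.to_numpy(), 0.25)


def test_growth_rate_proportions():
    gr = growth_rate_series(_core([3, 1]))
    assert np.allclose(gr.to_numpy(), [0.75, 0.25])


def test_growth_rate_sums_to_one():
    rng = np.random.default_rng(0)
    gr = growth_rate_series(_core(rng.uniform(0.1, 5, 50)))
    assert gr.sum() == pytest.approx(1.0, abs=1e-12)


def test_plot_growth_rate_mean_and_renormalization():
    a = growth_rate_series(_core([0.6, 0.4], tree_id="a"))
    b = growth_rate_series(_core([0.4, 0.6], tree_id="b"))
    c = growth_rate_series(_core([0.5, 0.5], tree_id="c"))
    gr = plot_growth_rate([a, b, c])
    assert np.allclose(gr.to_numpy(), [0.5, 0.5])
    # ragged spans: trimming to the common years must renormalize
    d = growth_rate_series(_core([1, 1, 1, 1], first_year=1979, tree_id="d"))
    gr2 = plot_growth_rate([a, b, d])
    assert gr2.sum() == pytest.approx(1.0, abs=1e-12)
    assert list(gr2.index) == [1980, 1981]


def test_plot_growth_rate_needs_three_trees():
    a = growth_rate_series(_core([1, 1]))
    with pytest.raises(ValueError):
        plot_growth_rate([a, a])


# ---------------------------------------------------------------------------
# back-casting
# ---------------------------------------------------------------------------

def test_backcast_noncored_uniform_growth():
    gr = pd.Series(np.full(20, 0.05), index=np.arange(1980, 2000))
    d = backcast_dbh(20.0, gr)
    assert d.loc[1989] == pytest.approx(10.0)   # halfway through
    assert d.loc[1999] == 20.0                  # exact closure


def test_backcast_cored_closure_and_arithmetic():
    gr = pd.Series(np.full(4, 0.25), index=np.arange(2000, 2004))
    widths = pd.Series([5.0, 5.0, 5.0, 5.0], index=np.arange(2000, 2004))
    d = backcast_dbh(10.0, gr, widths_mm=widths)
    # subtracting future increments: 2*width/10 = 0.1 cm per mm... 5mm->1cm diam
    assert d.loc[2003] == 10.0
    assert d.loc[2002] == pytest.approx(9.0)
    assert d.loc[2000] == pytest.approx(7.0)


def test_backcast_floors_at_minimum_diameter():
    gr = pd.Series(np.full(10, 0.1), index=np.arange(1990, 2000))
    d = backcast_dbh(5.0, gr)
    assert d.min() >= 1.0
    assert d.attrs["first_valid_year"] == 1991  # 5*0.2 = 1.0 cm


# ---------------------------------------------------------------------------
# annual CI
# ---------------------------------------------------------------------------

def test_annual_ci_homogeneous_plot_constant():
    """Identical trees growing in lockstep: DBH ratios cancel, CI constant."""
    rows = [("a", 10, 10, 20.0), ("b", 14, 10, 20.0), ("c", 10, 14, 20.0)]
    s = _stand(rows)
    years = np.arange(1990, 2000)
    hist = pd.DataFrame({t: np.linspace(5, 20, 10) for t in ("a", "b", "c")},
                        index=years)
    ci = annual_ci(s, hist, "a")
    assert np.allclose(ci.to_numpy(), ci.iloc[0])


def test_annual_ci_final_year_closes_on_inventory(plot_sim):
    sim = plot_sim
    cored = sim.cored_rings()
    dbh_hist, ci_hist = reconstruct_annual_ci(sim.stand, cored)
    final_year = ci_hist.index[-1]
    observed = hegyi_all(sim.stand).set_index("tree_id")["ci"]
    for tid in ci_hist.columns:
        assert ci_hist.loc[final_year, tid] == pytest.approx(observed[tid],
                                                             abs=1e-9)


def test_backcast_final_year_closure_exact(plot_sim):
    sim = plot_sim
    dbh_hist, _ = reconstruct_annual_ci(sim.stand, sim.cored_rings())
    final = dbh_hist.iloc[-1]
    obs = sim.stand.trees.set_index("tree_id")["dbh_cm"]
    for tid in dbh_hist.columns:
        assert final[tid] == obs[tid]  # bitwise: closure is enforced exactly


def test_reconstructed_dbh_monotone(plot_sim):
    dbh_hist, _ = reconstruct_annual_ci(plot_sim.stand, plot_sim.cored_rings())
    assert (dbh_hist.diff().dropna() >= -1e-12).all().all()


def test_reconstruction_recovers_true_ci(plot_sim):
    sim = plot_sim
    _, ci_hist = reconstruct_annual_ci(sim.stand, sim.cored_rings())
    true = sim.true_ci[ci_hist.columns]
    rel = ((ci_hist - true).abs() / true).stack().dropna()
    assert rel.median() < 0.10


def test_reconstruction_rejects_ingrowth():
    rows = [("a", 10, 10, 20.0), ("b", 14, 10, 20.0), ("c", 10, 14, 20.0),
            ("d", 14, 14, 20.0)]
    s = _stand(rows)
    cores = {t: _core(np.ones(5), first_year=2000, tree_id=t)
             for t in ("a", "b", "c")}
    with pytest.raises(ValueError, match="ingrowth"):
        reconstruct_annual_ci(s, cores)  # planting 1980, cores start 2000
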