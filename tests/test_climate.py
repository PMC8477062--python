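"""Climate derivatives: VPD, Thornthwaite PET, SPEI, trend/homogeneity screens."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dendrocomp as dc
from dendrocomp.climate import (ClimateSeries, double_mass, growing_season_spei,
                                mann_kendall, pet_thornthwaite, spei,
                                vpd_from_t_rh)


# ---------------------------------------------------------------------------
# VPD
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("t, rh, expected", [
    (25.0, 100.0, 0.0),        # saturated air
    (25.0, 50.0, 1.584),       # e_s(25)=3.168 kPa by Magnus, halved
    (0.0, 50.0, 0.3054),       # e_s(0)=0.6108 kPa
])
def test_vpd_reference_values(t, rh, expected):
    assert vpd_from_t_rh(t, rh) == pytest.approx(expected, abs=5e-4)


def test_vpd_rejects_bad_rh():
    with pytest.raises(ValueError):
        vpd_from_t_rh(20.0, 0.0)
    with pytest.raises(ValueError):
        vpd_from_t_rh(20.0, 101.0)


@given(t=st.floats(-30, 40), rh1=st.floats(1, 99), delta=st.floats(0.5, 30))
def test_vpd_nonnegative_and_decreasing_in_rh(t, rh1, delta):
    rh2 = min(rh1 + delta, 100.0)
    v1, v2 = vpd_from_t_rh(t, rh1), vpd_from_t_rh(t, rh2)
    assert v1 >= 0 and v2 >= 0
    assert v2 < v1


# ---------------------------------------------------------------------------
# Thornthwaite PET
# ---------------------------------------------------------------------------

def _make_climate(t_by_month, years=30, latitude=45.0):
    rows = []
    for y in range(2000, 2000 + years):
        for m in range(1, 13):
            rows.append((y, m, t_by_month[m - 1], 30.0, 60.0))
    df = pd.DataFrame(rows, columns=["year", "month", "tmean_c", "prcp_mm",
                                     "rh_pct"])
    return ClimateSeries(df, latitude=latitude)


def test_pet_zero_for_freezing_months():
    cs = _make_climate([-5.0] * 12)
    assert np.all(pet_thornthwaite(cs) == 0.0)


def test_pet_equatorial_constant_t_equal_for_30day_months():
    cs = _make_climate([20.0] * 12, latitude=0.0)
    pet = pet_thornthwaite(cs)[:12]
    months30 = [3, 5, 8, 10]  # Apr, Jun, Sep, Nov (0-based)
    vals = pet[months30]
    assert np.allclose(vals, vals[0], rtol=1e-3)


def test_pet_rejects_polar_latitude():
    with pytest.raises(ValueError):
        pet_thornthwaite(_make_climate([10.0] * 12, latitude=70.0))


def _thornthwaite_scalar(tmean_by_row, months, latitude):
    """Independent straight-from-the-textbook scalar reimplementation."""
    mid_doy = [15, 45, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349]
    ndays = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]
    clim = [np.mean([t for t, m in zip(tmean_by_row, months) if m == mm])
            for mm in range(1, 13)]
    heat = sum((max(t, 0.0) / 5.0) ** 1.514 for t in clim)
    a = 6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239
    out = []
    for t, m in zip(tmean_by_row, months):
        if t <= 0:
            pe = 0.0
        elif t < 26.5:
            pe = 16.0 * (10.0 * t / heat) ** a
        else:
            pe = -415.85 + 32.24 * t - 0.43 * t * t
        j = mid_doy[m - 1]
        decl = 0.409 * math.sin(2 * math.pi * j / 365 - 1.39)
        x = min(1.0, max(-1.0, -math.tan(math.radians(latitude)) * math.tan(decl)))
        n_hours = 24 / math.pi * math.acos(x)
        out.append(pe * (n_hours / 12.0) * (ndays[m - 1] / 30.0))
    return np.array(out)


def test_pet_matches_independent_reimplementation():
    rng = np.random.default_rng(0)
    base = 8 + 14 * np.cos(2 * np.pi * (np.arange(1, 13) - 7) / 12)
    t12 = base + rng.normal(0, 2, 12)
    cs = _make_climate(list(t12), years=20, latitude=42.0)
    got = pet_thornthwaite(cs)
    want = _thornthwaite_scalar(cs.data["tmean_c"].tolist(),
                                cs.data["month"].tolist(), 42.0)
    assert np.allclose(got, want, atol=1e-9)


# ---------------------------------------------------------------------------
# SPEI
# ---------------------------------------------------------------------------

def test_spei_startup_window_undefined(stationary_climate):
    s = spei(stationary_climate, scale=12)
    assert np.all(np.isnan(s[:11]))
    assert np.all(np.isfinite(s[11:]))


def test_spei_calendar_month_means_near_zero(stationary_climate):
    s = spei(stationary_climate, scale=1)
    months = stationary_climate.months
    for m in range(1, 13):
        assert abs(np.nanmean(s[months == m])) < 0.05


def test_spei_location_shift_invariance(stationary_climate):
    """Adding a constant to every month's precipitation only moves the
    fitted location parameter; the standardized index is unchanged."""
    s0 = spei(stationary_climate, scale=1)
    df = stationary_climate.data.copy()
    df["prcp_mm"] = df["prcp_mm"] + 50.0
    s1 = spei(ClimateSeries(df, latitude=stationary_climate.latitude), scale=1)
    assert np.nanmax(np.abs(s1 - s0)) < 0.02


def test_spei_unit_rescaling_invariance(stationary_climate):
    """mm → cm rescaling of the water balance refits scale/location only."""
    s0 = spei(stationary_climate, scale=1)
    df = stationary_climate.data.copy()
    from dendrocomp.climate import pet_thornthwaite as pt
    pet = pt(stationary_climate)
    # rescale P such that D -> D/10 exactly: P' = (P - PET)/10 + PET
    df["prcp_mm"] = (df["prcp_mm"] - pet) / 10.0 + pet
    s1 = spei(ClimateSeries(df, latitude=stationary_climate.latitude), scale=1)
    assert np.nanmax(np.abs(s1 - s0)) < 0.02


def test_growing_season_spei_standard_normal(stationary_climate):
    gs = growing_season_spei(stationary_climate)
    assert abs(gs.mean()) < 0.1
    assert 0.8 < gs.std() < 1.2


def test_growing_season_window_ignores_november(stationary_climate):
    gs0 = growing_season_spei(stationary_climate)
    df = stationary_climate.data.copy()
    year = int(df["year"].iloc[len(df) // 2])
    sel = (df["year"] == year) & (df["month"] == 11)
    df.loc[sel, "prcp_mm"] += 400.0
    gs1 = growing_season_spei(
        ClimateSeries(df, latitude=stationary_climate.latitude))
    assert gs1.loc[year] == pytest.approx(gs0.loc[year], abs=1e-12)


def test_imposed_drought_years_fall_below_threshold():
    cfg = dc.SimulationConfig(seed=4, drought_years=((1995, 2, 2.5),))
    gs = growing_season_spei(dc.gen_climate(cfg))
    assert gs.loc[1995] < -1.0
    assert gs.loc[1996] < -1.0


# ---------------------------------------------------------------------------
# Mann–Kendall
# ---------------------------------------------------------------------------

def test_mann_kendall_strictly_increasing():
    r = mann_kendall(np.arange(10, dtype=float))
    assert r.s == 45  # maximal S = n(n-1)/2
    assert r.p < 0.05
    assert r.direction == "increasing"


def test_mann_kendall_antisymmetry():
    rng = np.random.default_rng(1)
    x = rng.normal(size=30)
    a, b = mann_kendall(x), mann_kendall(x[::-1])
    assert a.s == -b.s
    assert a.p == pytest.approx(b.p)


def test_mann_kendall_constant_series():
    r = mann_kendall(np.ones(12))
    assert r.s == 0 and r.p == 1.0 and r.direction == "none"


def test_mann_kendall_null_pvalues_uniform():
    from scipy import stats
    rng = np.random.default_rng(7)
    ps = [mann_kendall(rng.normal(size=40)).p for _ in range(2000)]
    assert stats.kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# double mass
# ---------------------------------------------------------------------------

def test_double_mass_proportional_series_clean():
    rng = np.random.default_rng(3)
    ref = rng.gamma(4, 100, 40)
    r = double_mass(1.3 * ref, ref)
    assert not r.inhomogeneous
    assert r.slope_ratio == pytest.approx(1.0, abs=1e-9)


def test_double_mass_level_shift_located_at_midpoint():
    rng = np.random.default_rng(4)
    ref = rng.gamma(4, 100, 40)
    x = ref.copy()
    x[20:] *= 1.5
    r = double_mass(x, ref)
    assert r.inhomogeneous
    assert abs(r.breakpoint - 19) <= 2
    assert r.slope_ratio == pytest.approx(1.5, rel=0.1)


def test_double_mass_threshold_one_never_flags():
    rng = np.random.default_rng(5)
    ref = rng.gamma(4, 100, 40)
    x = ref.copy()
    x[20:] *= 1.5
    assert not double_mass(x, ref, threshold=1.0).inhomogeneous


def test_double_mass_zero_variance_reference_rejected():
    with pytest.raises(ValueError):
        double_mass(np.arange(20.0), np.zeros(20))
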