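"""Drought-event selection and Lloret resilience indices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dendrocomp.resilience import (DroughtEvent, ci_resilience_correlation,
                                   group_compare, moving_average_bai,
                                   resilience_indices, select_drought_events)


def _spei(drought_years, span=(1980, 2019)):
    years = np.arange(span[0], span[1] + 1)
    vals = np.where(np.isin(years, drought_years), -1.5, 0.3)
    return pd.Series(vals.astype(float), index=years)


def brute_force_events(drought_years, separation=3):
    """Independent oracle: iteratively merge events until stable."""
    events = [[y] for y in sorted(drought_years)]
    changed = True
    while changed:
        changed = False
        for i in range(len(events) - 1):
            if events[i + 1][0] - events[i][-1] <= separation:
                events[i] = events[i] + events[i + 1]
                del events[i + 1]
                changed = True
                break
    return [tuple(e) for e in events]


# ---------------------------------------------------------------------------
# event selection
# ---------------------------------------------------------------------------

def test_consecutive_run_is_one_event():
    ev = select_drought_events(_spei([2008, 2009]))
    assert len(ev) == 1 and ev[0].years == (2008, 2009)


def test_six_year_gap_gives_two_events():
    ev = select_drought_events(_spei([2008, 2014]))
    assert [e.years for e in ev] == [(2008,), (2014,)]
    assert [e.index for e in ev] == [1, 2]


def test_three_year_gap_merges():
    # separation of exactly 3 years is NOT more than 3 -> one event
    ev = select_drought_events(_spei([2008, 2011]))
    assert len(ev) == 1 and ev[0].years == (2008, 2011)


def test_no_drought_years_empty():
    assert select_drought_events(_spei([])) == []


def test_all_years_below_threshold_single_event():
    years = np.arange(1990, 2005)
    s = pd.Series(-1.4, index=years)
    ev = select_drought_events(s)
    assert len(ev) == 1 and len(ev[0].years) == len(years)


def test_event_selection_min_spei_and_order():
    s = _spei([1990, 2000])
    s.loc[1990] = -2.5
    ev = select_drought_events(s)
    assert ev[0].min_spei == -2.5
    assert [e.index for e in ev] == [1, 2]


@given(st.lists(st.integers(0, 11), min_size=0, max_size=12, unique=True))
def test_event_grouping_matches_bruteforce(pattern):
    years = [2000 + p for p in pattern]
    got = [e.years for e in select_drought_events(_spei(years, (1998, 2014)))]
    assert got == brute_force_events(years)


# ---------------------------------------------------------------------------
# moving average
# ---------------------------------------------------------------------------

def test_moving_average_constant_unchanged():
    s = pd.Series(4.0, index=np.arange(2000, 2010))
    assert np.allclose(moving_average_bai(s), 4.0)


def test_moving_average_linear_series():
    s = pd.Series([1.0, 2, 3, 4, 5], index=np.arange(2000, 2005))
    assert np.allclose(moving_average_bai(s).to_numpy(),
                       [1.5, 2.0, 3.0, 4.0, 4.5])


# ---------------------------------------------------------------------------
# resilience indices
# ---------------------------------------------------------------------------

def _bai(values, first=2000):
    return pd.Series(np.asarray(values, float),
                     index=np.arange(first, first + len(values)))


def test_constant_bai_gives_neutral_indices():
    ev = DroughtEvent(years=(2006,), min_spei=-1.5, index=1)
    ri = resilience_indices(_bai(np.full(15, 8.0)), ev)
    assert ri.rt == ri.rc == ri.rs == pytest.approx(1.0)
    assert ri.rrs == pytest.approx(0.0)


def test_reference_arithmetic():
    # BAI_pre = 10, BAI_D = 5, BAI_post = 8
    vals = [10, 10, 10, 5, 8, 8, 8]
    ev = DroughtEvent(years=(2003,), min_spei=-1.5, index=1)
    ri = resilience_indices(_bai(vals), ev)
    assert ri.rt == pytest.approx(0.5)
    assert ri.rc == pytest.approx(1.6)
    assert ri.rs == pytest.approx(0.8)
    assert ri.rrs == pytest.approx(0.3)


@given(st.lists(st.floats(0.5, 50.0), min_size=15, max_size=15))
def test_algebraic_identities(vals):
    ev = DroughtEvent(years=(2006, 2007), min_spei=-1.2, index=1)
    ri = resilience_indices(_bai(vals), ev)
    assert ri is not None
    assert ri.rrs == pytest.approx(ri.rs - ri.rt, abs=1e-12)
    assert ri.rs == pytest.approx(ri.rt * ri.rc, abs=1e-12)


def test_window_collision_shifts_then_gives_up():
    ev1 = DroughtEvent(years=(2005,), min_spei=-1.5, index=1)
    ev2 = DroughtEvent(years=(2010,), min_spei=-1.5, index=2)
    bai = _bai(np.full(20, 10.0))
    # post window of ev1 (2006-2008) is clean; pre window of ev2 (2007-2009)
    # is also clean -> both defined
    assert resilience_indices(bai, ev1, all_events=[ev1, ev2]) is not None
    assert resilience_indices(bai, ev2, all_events=[ev1, ev2]) is not None
    # an event at the very start of the series has no pre window at all
    ev0 = DroughtEvent(years=(2001,), min_spei=-1.5, index=1)
    assert resilience_indices(bai, ev0) is None


def test_edge_event_undefined():
    ev = DroughtEvent(years=(2018,), min_spei=-1.5, index=1)
    assert resilience_indices(_bai(np.full(19, 10.0)), ev) is None


# ---------------------------------------------------------------------------
# group comparison / correlation
# ---------------------------------------------------------------------------

def test_group_compare_identical_groups_p_near_one():
    rng = np.random.default_rng(0)
    vals = rng.normal(1.0, 0.1, 40)
    df = pd.DataFrame({"site": "s", "event_index": 1,
                       "ci_class": ["low"] * 20 + ["high"] * 20,
                       "rc": np.concatenate([vals[:20], vals[:20]])})
    _, pairs = group_compare(df, "rc")
    assert pairs["p"].iloc[0] > 0.99


def test_group_compare_detects_shift():
    rng = np.random.default_rng(1)
    hits = 0
    nsim = 50
    for _ in range(nsim):
        low = rng.normal(1.0, 0.1, 20)
        high = rng.normal(0.7, 0.1, 20)  # -30% shift, sd 10%
        df = pd.DataFrame({"site": "s", "event_index": 1,
                           "ci_class": ["low"] * 20 + ["high"] * 20,
                           "rc": np.concatenate([low, high])})
        _, pairs = group_compare(df, "rc")
        hits += pairs["p"].iloc[0] < 0.05
    assert hits >= 0.9 * nsim


def test_group_compare_row_count_and_singleton_drop():
    df = pd.DataFrame({
        "site": ["s1"] * 7, "event_index": [1] * 4 + [2] * 3,
        "ci_class": ["low", "low", "high", "high", "low", "low", "high"],
        "rc": [1.0, 1.1, 0.8, 0.9, 1.0, 1.05, 0.85]})
    with pytest.warns(UserWarning, match="dropped"):
        summary, _ = group_compare(df, "rc")
    # event 2 'high' is a singleton -> dropped; 3 groups remain
    assert len(summary) == 3


def test_ci_correlation_affine_invariance():
    rng = np.random.default_rng(2)
    ci = rng.uniform(0.5, 4.0, 30)
    df = pd.DataFrame({"event_index": 1, "ci": ci,
                       "rt": 1 - 0.05 * ci + rng.normal(0, 0.05, 30),
                       "rc": 1 - 0.10 * ci + rng.normal(0, 0.05, 30),
                       "rs": 1 - 0.10 * ci + rng.normal(0, 0.05, 30),
                       "rrs": -0.10 * ci + rng.normal(0, 0.05, 30)})
    r0 = ci_resilience_correlation(df)
    df2 = df.copy()
    df2["ci"] = 10.0 * df2["ci"] + 3.0
    r1 = ci_resilience_correlation(df2)
    assert np.allclose(r0["r"], r1["r"], atol=1e-12)


def test_ci_correlation_requires_variance():
    df = pd.DataFrame({"event_index": 1, "ci": np.ones(12),
                       "rt": np.random.default_rng(0).normal(1, .1, 12),
                       "rc": 1.0, "rs": 1.0, "rrs": 0.0})
    with pytest.raises(ValueError, match="zero variance"):
        ci_resilience_correlation(df)
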