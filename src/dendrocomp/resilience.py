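"""Drought events and Lloret resistance/recovery/resilience indices.

A calendar year is a severe drought year when its growing-season SPEI
(April–October, 7-month window) falls below −1. Drought years are grouped
into events; because drought legacy effects persist for a year or two, two
events must be separated by more than 3 non-drought years — runs closer
than that are merged into one multi-year event.

For a tree with basal-area increment series BAI_t and an event D, with
BAI_pre / BAI_post the mean BAI over the 3 years immediately before /
after the event and BAI_D the mean over the event years:

    resistance          Rt  = BAI_D    / BAI_pre
    recovery            Rc  = BAI_post / BAI_D
    resilience          Rs  = BAI_post / BAI_pre
    relative resilience RRs = (BAI_post − BAI_D) / BAI_pre

so RRs = Rs − Rt and Rs = Rt·Rc identically. Indices are computed per tree
on raw (unsmoothed) BAI; the 3-year moving average is a display and event-
inspection aid. If another event intrudes into a pre/post window, the
window slides to the nearest 3 clean years within 5 years of the event,
else the index is undefined for that tree/event.

Group contrasts (by competition class, site, event ordinal) are summarized
with means ± sd and pairwise Welch t-tests. Welch is a deliberate stand-in
for the post-hoc LSD ANOVA machinery of classical stand comparisons and is
labelled as such in the output metadata.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DroughtEvent",
    "ResilienceIndices",
    "select_drought_events",
    "moving_average_bai",
    "resilience_indices",
    "group_compare",
    "ci_resilience_correlation",
]

SPEI_THRESHOLD = -1.0
EVENT_SEPARATION_YEARS = 3
WINDOW_YEARS = 3
MAX_WINDOW_SHIFT = 2  # pre/post window may slide this far to avoid other events

INDEX_NAMES = ("rt", "rc", "rs", "rrs")


@dataclass(frozen=True)
class DroughtEvent:
    """One severe-drought event: its member drought years and severity."""

    years: tuple
    min_spei: float
    index: int  # ordinal at the site, 1-based, chronological

    @property
    def start(self) -> int:
        return self.years[0]

    @property
    def end(self) -> int:
        return self.years[-1]


@dataclass
class ResilienceIndices:
    """Lloret indices of one tree for one event (3-year windows)."""

    rt: float
    rc: float
    rs: float
    rrs: float
    bai_pre: float
    bai_d: float
    bai_post: float
    window: int = WINDOW_YEARS


def select_drought_events(gs_spei: pd.Series,
                          threshold: float = SPEI_THRESHOLD,
                          separation: int = EVENT_SEPARATION_YEARS,
                          ) -> list[DroughtEvent]:
    """Group sub-threshold years into events; merge runs separated ≤ 3 yr.

    ``gs_spei`` is a year-indexed growing-season SPEI series. Years with
    SPEI < ``threshold`` are drought years; consecutive drought years with
    gaps of at most ``separation`` years belong to the same event (two
    events must be separated by *more* than ``separation`` years). Events
    are returned chronologically with 1-based ordinals; the empty list is a
    valid outcome.
    """
    if len(gs_spei) < 10:
        raise ValueError("need at least 10 years of growing-season SPEI")
    s = gs_spei.dropna().sort_index()
    dyears = [int(y) for y, v in s.items() if v < threshold]
    if not dyears:
        return []
    groups: list[list[int]] = [[dyears[0]]]
    for y in dyears[1:]:
        if y - groups[-1][-1] <= separation:
            groups[-1].append(y)
        else:
            groups.append([y])
    events = []
    for k, g in enumerate(groups, start=1):
        events.append(DroughtEvent(years=tuple(g),
                                   min_spei=float(s.loc[list(g)].min()),
                                   index=k))
    return events


def moving_average_bai(bai: pd.Series, window: int = 3) -> pd.Series:
    """Centred ``window``-year moving average; endpoints use 2-year means."""
    if len(bai) < window:
        raise ValueError("series shorter than the smoothing window")
    out = bai.sort_index().rolling(window, center=True, min_periods=2).mean()
    out.name = bai.name
    return out


def _clean_window(years_avail: pd.Index, blocked: set[int], first: int,
                  window: int, shift_dir: int, max_shift: int) -> list[int] | None:
    """Find ``window`` consecutive clean years [first, first+window), sliding
    away from the event (by ``shift_dir`` steps) up to ``max_shift`` years."""
    for shift in range(max_shift + 1):
        base = first + shift_dir * shift
        cand = list(range(base, base + window))
        if all(y in years_avail and y not in blocked for y in cand):
            return cand
    return None


def resilience_indices(bai: pd.Series, event: DroughtEvent,
                       window: int = WINDOW_YEARS,
                       all_events: list[DroughtEvent] | None = None,
                       smoothed: bool = False,
                       max_shift: int = MAX_WINDOW_SHIFT,
                       ) -> ResilienceIndices | None:
    """Lloret indices of one BAI series for one event; None when undefined.

    ``all_events`` lets the pre/post windows avoid the drought years of
    *other* events (windows slide outward by up to ``max_shift`` years to
    find 3 clean years; only the event years themselves are strictly
    excluded). ``smoothed=True`` computes the indices on the 3-year moving
    average instead of raw BAI.
    """
    series = moving_average_bai(bai, window=3) if smoothed else bai.sort_index()
    years = series.dropna().index

    event_years = [y for y in event.years if y in years]
    if not event_years:
        return None
    blocked: set[int] = set()
    for ev in all_events or []:
        if ev.index != event.index:
            blocked.update(ev.years)

    pre = _clean_window(years, blocked, event.start - window, window, -1,
                        max_shift)
    post = _clean_window(years, blocked, event.end + 1, window, +1, max_shift)
    if pre is None or post is None:
        return None

    bai_pre = float(series.loc[pre].mean())
    bai_d = float(series.loc[event_years].mean())
    bai_post = float(series.loc[post].mean())
    if bai_pre <= 0 or bai_d <= 0:
        return None
    return ResilienceIndices(rt=bai_d / bai_pre, rc=bai_post / bai_d,
                             rs=bai_post / bai_pre,
                             rrs=(bai_post - bai_d) / bai_pre,
                             bai_pre=bai_pre, bai_d=bai_d, bai_post=bai_post,
                             window=window)


def group_compare(records: pd.DataFrame, value: str,
                  by: tuple = ("site", "event_index", "ci_class"),
                  min_group: int = 2) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group means ± sd and pairwise Welch t-tests of one resilience index.

    ``records`` is a long frame with one row per tree × event holding the
    grouping columns and the index value. Groups smaller than ``min_group``
    are dropped with a warning. Pairwise tests compare competition classes
    within each (site, event) cell. Welch's t replaces the classical
    post-hoc LSD comparison and the output is labelled accordingly
    (``summary.attrs['test']``).
    """
    by = [c for c in by if c in records.columns]
    cls_col = by[-1]
    outer = by[:-1]
    df = records.dropna(subset=[value])

    summary_rows, pair_rows = [], []
    grouping = df.groupby(outer) if outer else [((), df)]
    for key, sub in grouping:
        key = key if isinstance(key, tuple) else (key,)
        cells = {}
        for cls, cell in sub.groupby(cls_col):
            if len(cell) < min_group:
                warnings.warn(f"group {key + (cls,)} has n={len(cell)} < "
                              f"{min_group}; dropped")
                continue
            cells[cls] = cell[value].to_numpy(dtype=float)
            summary_rows.append(dict(zip(outer, key), **{
                cls_col: cls, "mean": cells[cls].mean(),
                "sd": cells[cls].std(ddof=1), "n": len(cells[cls])}))
        for a, b in itertools.combinations(sorted(cells), 2):
            t, p = stats.ttest_ind(cells[a], cells[b], equal_var=False)
            pair_rows.append(dict(zip(outer, key), **{
                "group_a": a, "group_b": b, "t": float(t), "p": float(p)}))
    summary = pd.DataFrame(summary_rows)
    pairs = pd.DataFrame(pair_rows)
    summary.attrs["test"] = "Welch pairwise t (stand-in for post-hoc LSD)"
    return summary, pairs


def ci_resilience_correlation(records: pd.DataFrame, ci_col: str = "ci",
                              indices: tuple = INDEX_NAMES,
                              by_event: str = "event_index") -> pd.DataFrame:
    """Pearson correlation of modeled CI with each index, per event.

    ``records`` holds one row per tree × event with the tree's modeled
    (reconstructed) CI and its resilience indices; trees are pooled across
    competition classes (≥ 10 per event required). Returns a long frame
    (event, index, r, p, n).
    """
    rows = []
    for ev, sub in records.groupby(by_event):
        ci = sub[ci_col].to_numpy(dtype=float)
        if len(sub) < 10:
            raise ValueError(f"event {ev}: need >= 10 pooled trees")
        if np.ptp(ci) == 0:
            raise ValueError(f"event {ev}: zero variance in CI")
        for name in indices:
            vals = sub[name].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            if ok.sum() < 10 or np.ptp(vals[ok]) == 0:
                rows.append((ev, name, np.nan, np.nan, int(ok.sum())))
                continue
            r, p = stats.pearsonr(ci[ok], vals[ok])
            rows.append((ev, name, float(r), float(p), int(ok.sum())))
    return pd.DataFrame(rows, columns=["event_index", "index", "r", "p", "n"])
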