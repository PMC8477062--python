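"""Monthly climate derivatives for dendroclimatology.

This module turns monthly station records (mean temperature, precipitation
total, relative humidity) into the derived quantities used throughout the
pipeline:

* vapour pressure deficit (VPD) from temperature and relative humidity,
* potential evapotranspiration (PET) by the Thornthwaite water-balance
  method (temperature and latitude only),
* the standardized precipitation-evapotranspiration index (SPEI) at an
  arbitrary monthly aggregation scale, standardized through a 3-parameter
  log-logistic distribution fitted by unbiased probability-weighted moments,
* a one-value-per-year growing-season SPEI (April–October window),
* Mann–Kendall trend tests and double-mass homogeneity screening for
  station-record quality control.

The SPEI follows the usual construction: the climatic water balance
``D = P − PET`` is summed over a backward window of ``k`` months, the window
sums belonging to the same calendar month are fitted with a log-logistic
distribution, and the fitted cumulative probability is mapped through the
standard normal quantile function. The log-logistic parameters are obtained
in closed form from the first three unbiased probability-weighted moments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gamma as _gamma_fn

__all__ = [
    "ClimateSeries",
    "TrendTestResult",
    "DoubleMassResult",
    "saturation_vapor_pressure",
    "vpd_from_t_rh",
    "pet_thornthwaite",
    "climatic_balance",
    "spei",
    "growing_season_spei",
    "mann_kendall",
    "double_mass",
]

REQUIRED_COLUMNS = ("year", "month", "tmean_c", "prcp_mm", "rh_pct")

#: mid-month day-of-year used for the day-length correction (non-leap year)
_MID_MONTH_DOY = np.array([15, 45, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349])
_DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

# cumulative-probability clip for the normal quantile map; keeps imposed
# extreme droughts finite (|SPEI| <= ~4.75) without affecting the bulk
_P_CLIP = 1e-6


@dataclass
class ClimateSeries:
    """Contiguous monthly climate record for one station/site.

    ``data`` must hold one row per month with columns
    ``year, month, tmean_c, prcp_mm, rh_pct`` (optionally ``tmax_c``,
    ``tmin_c``, ``wind_ms``, ``pres_hpa``). Months must be contiguous with
    no gaps; precipitation must be non-negative and RH in (0, 100].
    """

    data: pd.DataFrame
    latitude: float = 45.0

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"climate table missing columns: {missing}")
        if len(df) < 12:
            raise ValueError("climate record shorter than 12 months")
        seq = df["year"].to_numpy() * 12 + (df["month"].to_numpy() - 1)
        if np.any(np.diff(seq) != 1):
            raise ValueError("climate months are not contiguous")
        if np.any(df["prcp_mm"].to_numpy() < 0):
            raise ValueError("negative precipitation")
        rh = df["rh_pct"].to_numpy(dtype=float)
        if np.any(rh <= 0) or np.any(rh > 100):
            raise ValueError("relative humidity must lie in (0, 100]")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def years(self) -> np.ndarray:
        return self.data["year"].to_numpy()

    @property
    def months(self) -> np.ndarray:
        return self.data["month"].to_numpy()

    # convenience delegates ------------------------------------------------
    def vpd(self) -> np.ndarray:
        return vpd_from_t_rh(self.data["tmean_c"].to_numpy(dtype=float),
                             self.data["rh_pct"].to_numpy(dtype=float))

    def pet(self) -> np.ndarray:
        return pet_thornthwaite(self)

    def balance(self) -> np.ndarray:
        return climatic_balance(self)

    def spei(self, scale: int = 1) -> np.ndarray:
        return spei(self, scale)

    def growing_season_spei(self, start_month: int = 4, end_month: int = 10) -> pd.Series:
        return growing_season_spei(self, start_month=start_month, end_month=end_month)


# ---------------------------------------------------------------------------
# VPD
# ---------------------------------------------------------------------------

def saturation_vapor_pressure(t_c):
    """Saturation vapour pressure (kPa) by the Magnus formula."""
    t = np.asarray(t_c, dtype=float)
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def vpd_from_t_rh(t_c, rh_pct):
    """Vapour pressure deficit (kPa) from air temperature (°C) and RH (%).

    VPD = e_s(T) * (1 − RH/100), with e_s by the Magnus formula. RH must be
    in (0, 100]; saturated air gives exactly 0.
    """
    rh = np.asarray(rh_pct, dtype=float)
    if np.any(rh <= 0) or np.any(rh > 100):
        raise ValueError("RH must lie in (0, 100]")
    out = saturation_vapor_pressure(t_c) * (1.0 - rh / 100.0)
    if np.isscalar(t_c) and np.isscalar(rh_pct):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Thornthwaite PET
# ---------------------------------------------------------------------------

def _day_length_hours(latitude: float, month_idx: np.ndarray) -> np.ndarray:
    """Mean day length (h) at mid-month; month_idx is 0-based calendar month."""
    phi = math.radians(latitude)
    j = _MID_MONTH_DOY[month_idx]
    decl = 0.409 * np.sin(2.0 * np.pi * j / 365.0 - 1.39)
    x = np.clip(-math.tan(phi) * np.tan(decl), -1.0, 1.0)
    ws = np.arccos(x)
    return 24.0 / np.pi * ws


def pet_thornthwaite(series: ClimateSeries) -> np.ndarray:
    """Monthly potential evapotranspiration (mm) by Thornthwaite's method.

    The annual heat index is computed from the record's mean monthly
    temperature climatology. Months with mean temperature <= 0 °C get
    PET = 0; the hot-month polynomial replaces the power law above 26.5 °C.
    Day-length correction uses the latitude of the series; latitudes beyond
    ±66° are outside the formula's domain and rejected.
    """
    lat = series.latitude
    if not -66.0 <= lat <= 66.0:
        raise ValueError("latitude outside [-66, 66] degrees")
    df = series.data
    t = df["tmean_c"].to_numpy(dtype=float)
    month_idx = df["month"].to_numpy() - 1

    clim = np.full(12, np.nan)
    for m in range(12):
        clim[m] = t[month_idx == m].mean()
    heat = np.sum(np.power(np.maximum(clim, 0.0) / 5.0, 1.514))
    if heat <= 0:
        return np.zeros_like(t)
    a = (6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239)

    pe = np.zeros_like(t)
    warm = (t > 0) & (t < 26.5)
    hot = t >= 26.5
    pe[warm] = 16.0 * np.power(10.0 * t[warm] / heat, a)
    pe[hot] = -415.85 + 32.24 * t[hot] - 0.43 * t[hot] ** 2

    ndays = _DAYS_IN_MONTH[month_idx]
    corr = _day_length_hours(lat, month_idx) / 12.0 * ndays / 30.0
    return pe * corr


def climatic_balance(series: ClimateSeries) -> np.ndarray:
    """Monthly climatic water balance D = P − PET (mm)."""
    return series.data["prcp_mm"].to_numpy(dtype=float) - pet_thornthwaite(series)


# ---------------------------------------------------------------------------
# log-logistic fit by unbiased probability-weighted moments
# ---------------------------------------------------------------------------

def _pwm_unbiased(x: np.ndarray) -> tuple[float, float, float]:
    """First three unbiased PWMs b_r = E[X F(X)^r] of a sample."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    i = np.arange(1, n + 1)
    b0 = x.mean()
    b1 = np.sum((i - 1) * x) / (n * (n - 1))
    b2 = np.sum((i - 1) * (i - 2) * x) / (n * (n - 1) * (n - 2))
    return b0, b1, b2


def _fit_log_logistic(x: np.ndarray):
    """Fit the log-logistic family by unbiased PWMs (L-moments).

    The fit uses the generalized-logistic parametrization (shape k, scale
    alpha, location xi), which on the positive-skew branch (k < 0,
    k = −1/β) *is* the 3-parameter log-logistic
    F(x) = [1 + (α′/(x − loc))^β]^{-1}, and extends continuously to
    negatively skewed samples — which arise here when severe droughts put
    heavy mass in the left tail of the climatic balance. L-moments from the
    PWMs: λ1 = b0, λ2 = 2b1 − b0, λ3 = 6b2 − 6b1 + b0; then k = −λ3/λ2,
    α = λ2·sin(kπ)/(kπ), ξ = λ1 − α(1/k − π/sin(kπ)).
    Returns None for degenerate or infeasible (|k| ≥ 1) samples.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 8 or np.ptp(x) == 0:
        return None
    b0, b1, b2 = _pwm_unbiased(x)
    lam1 = b0
    lam2 = 2.0 * b1 - b0
    lam3 = 6.0 * b2 - 6.0 * b1 + b0
    if lam2 <= 0:
        return None
    k = -lam3 / lam2
    if not np.isfinite(k) or abs(k) >= 0.98:
        return None
    if abs(k) < 1e-8:
        alpha = lam2
        xi = lam1
        k = 0.0
    else:
        kp = k * np.pi
        alpha = lam2 * math.sin(kp) / kp
        xi = lam1 - alpha * (1.0 / k - np.pi / math.sin(kp))
    if not np.isfinite(alpha) or alpha <= 0:
        return None
    return k, alpha, xi


def _log_logistic_cdf(x: np.ndarray, k: float, alpha: float, xi: float) -> np.ndarray:
    """Generalized-logistic CDF (log-logistic for k < 0)."""
    x = np.asarray(x, dtype=float)
    if k == 0.0:
        y = (x - xi) / alpha
    else:
        # clamping `arg` to a tiny positive value makes the CDF saturate
        # correctly outside the support (0 at the k<0 lower bound, 1 at the
        # k>0 upper bound)
        arg = np.maximum(1.0 - k * (x - xi) / alpha, 1e-300)
        y = -np.log(arg) / k
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-y))


def _standardize(values: np.ndarray) -> np.ndarray:
    """Fit log-logistic to `values` and map to standard normal deviates.

    Returns NaN for all entries when the fit is infeasible (degenerate
    sample)."""
    fit = _fit_log_logistic(values)
    if fit is None:
        return np.full(len(values), np.nan)
    p = _log_logistic_cdf(values, *fit)
    p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    return stats.norm.ppf(p)


# ---------------------------------------------------------------------------
# SPEI
# ---------------------------------------------------------------------------

def spei(series: ClimateSeries, scale: int = 1) -> np.ndarray:
    """SPEI at ``scale`` months, aligned to the input rows.

    The first ``scale − 1`` months are undefined (NaN), as are months whose
    calendar-month sample is degenerate. Each calendar month (of the window
    end) is standardized separately over the whole record.
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")
    d = climatic_balance(series)
    n = len(d)
    if scale > n:
        raise ValueError("scale longer than record")
    csum = np.concatenate([[0.0], np.cumsum(d)])
    rolled = np.full(n, np.nan)
    rolled[scale - 1:] = csum[scale:] - csum[:-scale]

    months = series.months
    out = np.full(n, np.nan)
    for m in range(1, 13):
        mask = (months == m) & np.isfinite(rolled)
        if mask.sum() == 0:
            continue
        vals = rolled[mask]
        z = _standardize(vals)
        if np.all(np.isnan(z)):
            warnings.warn(f"degenerate climatic balance for calendar month {m}; "
                          "SPEI undefined there")
        out[mask] = z
    return out


def growing_season_spei(series: ClimateSeries, start_month: int = 4,
                        end_month: int = 10) -> pd.Series:
    """One SPEI value per year for the growing-season window (default Apr–Oct).

    The window sum of the climatic balance (April through October of the
    same year) is computed for every year with complete coverage, the
    log-logistic is fitted to that one-per-year sample, and each year's sum
    is mapped to a standard normal deviate. Years with incomplete windows
    are omitted.
    """
    df = series.data
    d = climatic_balance(series)
    sums: dict[int, float] = {}
    nmonths = end_month - start_month + 1
    for year, grp in df.groupby("year"):
        idx = grp.index[(grp["month"] >= start_month) & (grp["month"] <= end_month)]
        if len(idx) == nmonths:
            sums[int(year)] = float(d[idx].sum())
    if len(sums) < 8:
        raise ValueError("too few complete growing seasons for SPEI fit")
    years = np.array(sorted(sums))
    vals = np.array([sums[y] for y in years])
    z = _standardize(vals)
    return pd.Series(z, index=years, name="gs_spei")


# ---------------------------------------------------------------------------
# homogeneity / trend screens
# ---------------------------------------------------------------------------

@dataclass
class TrendTestResult:
    """Mann–Kendall trend test outcome."""

    s: int
    z: float
    p: float
    direction: str
    n: int


def mann_kendall(x, alpha: float = 0.05) -> TrendTestResult:
    """Mann–Kendall test for a monotonic trend.

    S = Σ_{i<j} sign(x_j − x_i); the variance uses the tie correction and z
    is continuity-corrected. ``direction`` is 'increasing'/'decreasing' when
    the two-sided p is below ``alpha``, else 'none'.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("Mann-Kendall needs n >= 8")
    sgn = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(sgn, 1).sum())

    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var <= 0:  # all values equal
        return TrendTestResult(s=0, z=0.0, p=1.0, direction="none", n=n)
    if s > 0:
        z = (s - 1) / math.sqrt(var)
    elif s < 0:
        z = (s + 1) / math.sqrt(var)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    if p < alpha and s > 0:
        direction = "increasing"
    elif p < alpha and s < 0:
        direction = "decreasing"
    else:
        direction = "none"
    return TrendTestResult(s=s, z=float(z), p=float(p), direction=direction, n=n)


@dataclass
class DoubleMassResult:
    """Double-mass homogeneity screen outcome.

    ``breakpoint`` is the 0-based index of the last observation of the first
    segment of the best two-segment fit of cumulative candidate vs
    cumulative reference; ``slope_ratio`` = second-segment slope / first-
    segment slope.
    """

    breakpoint: int
    slope_ratio: float
    inhomogeneous: bool
    sse: float


def _segment_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS line fit; returns (slope, sse)."""
    a = np.vstack([x, np.ones_like(x)]).T
    coef, res, _, _ = np.linalg.lstsq(a, y, rcond=None)
    sse = float(res[0]) if len(res) else float(np.sum((y - a @ coef) ** 2))
    return float(coef[0]), sse


def double_mass(x, reference, threshold: float = 0.10) -> DoubleMassResult:
    """Two-segment double-mass screen of ``x`` against a homogeneous reference.

    Cumulative sums of both series are formed and the cumulative candidate
    is fitted piecewise-linearly (two segments) against the cumulative
    reference; the break minimizing total SSE is reported. The record is
    flagged inhomogeneous when the segment-slope ratio deviates from one by
    more than ``threshold`` (default 10%).
    """
    x = np.asarray(x, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if len(x) != len(ref):
        raise ValueError("series lengths differ")
    if len(x) < 8:
        raise ValueError("double-mass needs n >= 8")
    if np.ptp(ref) == 0 and ref[0] == 0:
        raise ValueError("zero-variance reference")
    cx = np.cumsum(x)
    cr = np.cumsum(ref)
    if np.ptp(cr) == 0:
        raise ValueError("zero-variance reference")

    best = None
    for k in range(2, len(x) - 3):
        s1, e1 = _segment_fit(cr[: k + 1], cx[: k + 1])
        s2, e2 = _segment_fit(cr[k + 1:], cx[k + 1:])
        sse = e1 + e2
        if best is None or sse < best[0]:
            best = (sse, k, s1, s2)
    sse, k, s1, s2 = best
    ratio = s2 / s1 if s1 != 0 else math.inf
    flag = abs(ratio - 1.0) > threshold
    return DoubleMassResult(breakpoint=k, slope_ratio=float(ratio),
                            inhomogeneous=bool(flag), sse=sse)
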