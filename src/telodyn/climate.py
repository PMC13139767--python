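"""Extreme-weather indices and lagged correlation with annual mean rTL.

Heatwave and drought months are defined by decile thresholds: a month is a
heatwave month if its maximum or mean temperature lies in the top 10% of
that calendar month's distribution across years (per station), and a
drought month if its total precipitation lies in the bottom 10%. Annual
counts of flagged months are min-max normalised and cross-correlated with
the annual mean rTL z-score at lags up to +/-6 years; significance of the
chosen-lag correlation is assessed by permuting the year assignment of the
rTL series (5000 permutations by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WEATHER_COLUMNS = ("station", "year", "month", "tmax", "tmean", "precip")


@dataclass
class CcfResult:
    lags: np.ndarray
    r: np.ndarray
    threshold: float  # +/- 1.96 / sqrt(n)
    n: int
    perm_p: float | None = None
    n_perm: int | None = None
    seed: int | None = None

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"lag": self.lags, "r": self.r, "threshold": self.threshold})


def _stratum_flags(values: np.ndarray, q: float, tail: str) -> np.ndarray:
    """Decile flags within one (station, calendar-month) stratum.

    Ties at a constant stratum never flag: an extreme must differ from the
    opposite end of the stratum's range.
    """
    v = np.asarray(values, float)
    if tail == "upper":
        thr = np.quantile(v, 1.0 - q)
        return (v >= thr) & (v > v.min())
    thr = np.quantile(v, q)
    return (v <= thr) & (v < v.max())


def flag_extreme_months(
    weather: pd.DataFrame, q: float = 0.10, min_years: int = 10, pool_months: bool = False
) -> pd.DataFrame:
    """Flag heatwave and drought months against per-calendar-month deciles.

    Thresholds are empirical quantiles (linear interpolation) computed per
    station and calendar month across years, so extremes are assessed
    relative to that month's own climatology (``pool_months=True`` pools all
    months instead). Strata with fewer than ``min_years`` records are
    skipped with a warning.

    Returns the input rows with boolean ``heatwave`` and ``drought`` columns.
    """
    missing = set(WEATHER_COLUMNS) - set(weather.columns)
    if missing:
        raise ValueError(f"weather table missing columns {sorted(missing)}")
    out = weather.copy()
    out["heatwave"] = False
    out["drought"] = False
    strata = ["station"] if pool_months else ["station", "month"]
    for key, idx in out.groupby(strata).groups.items():
        sub = out.loc[idx]
        if len(sub) < min_years:
            logger.warning("stratum %s has %d records (< %d); skipped", key, len(sub), min_years)
            continue
        hot = _stratum_flags(sub["tmax"].to_numpy(), q, "upper") | _stratum_flags(
            sub["tmean"].to_numpy(), q, "upper"
        )
        dry = _stratum_flags(sub["precip"].to_numpy(), q, "lower")
        out.loc[idx, "heatwave"] = hot
        out.loc[idx, "drought"] = dry
    return out


def minmax_normalise(x: np.ndarray) -> np.ndarray:
    """Scale a series to [0, 1]; constant series are returned unchanged
    (with a warning) since the normalisation is undefined."""
    x = np.asarray(x, float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        logger.warning("min-max normalisation of a constant series; returned unscaled")
        return x.copy()
    return (x - lo) / (hi - lo)


def annual_event_counts(flags: pd.DataFrame) -> pd.DataFrame:
    """Annual heatwave/drought month counts, averaged across stations.

    Returns one row per year with heatwave_count, drought_count and their
    min-max normalised versions.
    """
    per_station = (
        flags.groupby(["station", "year"])[["heatwave", "drought"]].sum().reset_index()
    )
    annual = (
        per_station.groupby("year")[["heatwave", "drought"]].mean().reset_index()
    ).rename(columns={"heatwave": "heatwave_count", "drought": "drought_count"})
    annual["heatwave_norm"] = minmax_normalise(annual["heatwave_count"].to_numpy())
    annual["drought_norm"] = minmax_normalise(annual["drought_count"].to_numpy())
    return annual


def annual_mean_z(samples: pd.DataFrame, z_col: str = "rtl_z") -> pd.DataFrame:
    """Per-year mean rTL z-score with sample counts and a min-max normalised
    column for plotting/CCF parity with the event series."""
    if samples.empty:
        raise ValueError("no samples")
    g = samples.dropna(subset=[z_col]).groupby("year")[z_col]
    out = g.agg(mean_z="mean", n="count").reset_index()
    out["mean_z_norm"] = minmax_normalise(out["mean_z"].to_numpy())
    return out


def cross_correlation(x: np.ndarray, y: np.ndarray, max_lag: int = 6) -> CcfResult:
    """Sample cross-correlation at integer lags -max_lag..max_lag.

    r(k) = sum_t (x_{t+k} - xbar)(y_t - ybar) / (n s_x s_y) with overall
    means and population (denominator n) standard deviations, the standard
    time-series convention; r(0) = Pearson r exactly. The approximate white
    -noise significance threshold is +/- 1.96/sqrt(n).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("series must be aligned and equal length")
    n = len(x)
    if n < max_lag + 3:
        raise ValueError(f"series too short (n={n}) for max_lag={max_lag}")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance series")
    xc, yc = x - x.mean(), y - y.mean()
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.empty(len(lags))
    for i, k in enumerate(lags):
        if k >= 0:
            r[i] = np.sum(xc[k:] * yc[: n - k]) / (n * sx * sy)
        else:
            r[i] = np.sum(xc[: n + k] * yc[-k:]) / (n * sx * sy)
    return CcfResult(lags=lags, r=r, threshold=1.96 / np.sqrt(n), n=n)


def _r_at_lag(xc: np.ndarray, yc: np.ndarray, n: int, sx: float, sy: float, k: int) -> float:
    if k >= 0:
        return float(np.sum(xc[k:] * yc[: n - k]) / (n * sx * sy))
    return float(np.sum(xc[: n + k] * yc[-k:]) / (n * sx * sy))


def permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    lag: int = 0,
    n_perm: int = 5000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation p-value for the cross-correlation at one lag.

    The year assignment of ``y`` is randomly permuted ``n_perm`` times and
    the two-sided p-value is (1 + #{|r*| >= |r_obs|}) / (n_perm + 1).
    Returns (r_obs, p).
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is small; p-value resolution is coarse", n_perm)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance series")
    xc = x - x.mean()
    yc = y - y.mean()
    r_obs = _r_at_lag(xc, yc, n, sx, sy, lag)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        yp = yc[rng.permutation(n)]
        if abs(_r_at_lag(xc, yp, n, sx, sy, lag)) >= abs(r_obs) - 1e-15:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return r_obs, float(p)


def climate_rtl_analysis(
    weather: pd.DataFrame,
    samples: pd.DataFrame,
    q: float = 0.10,
    max_lag: int = 6,
    n_perm: int = 5000,
    seed: int | None = None,
    min_years: int = 10,
) -> dict:
    """Full extreme-weather vs rTL workflow for one study.

    Flags extreme months, builds annual event and rTL series on the common
    years, computes the CCF for drought and heatwave counts against annual
    mean z, and permutation-tests the zero-lag correlations.
    """
    flags = flag_extreme_months(weather, q=q, min_years=min_years)
    events = annual_event_counts(flags)
    zs = annual_mean_z(samples)
    merged = events.merge(zs, on="year", how="inner").sort_values("year")
    out = {"events": events, "annual_z": zs, "merged": merged}
    for kind in ("drought", "heatwave"):
        x = merged[f"{kind}_count"].to_numpy()
        z = merged["mean_z"].to_numpy()
        ccf = cross_correlation(x, z, max_lag=min(max_lag, len(merged) - 3))
        r_obs, p = permutation_test(x, z, lag=0, n_perm=n_perm, seed=seed)
        ccf.perm_p, ccf.n_perm, ccf.seed = p, n_perm, seed
        out[f"{kind}_ccf"] = ccf
    return out
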