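"""Environmental analysis of daily flower-opening times.

Covers the humidity deficit, daytime-mean weather factors and their Pearson
correlation with FOT, a trailing 1-h sliding-window temperature sensitivity
scan over clock times, temperature at FOT, the hot-day temperature-drop
trigger analysis, and pairwise rank-sum group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date, datetime, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "UndefinedCorrelation",
    "humidity_deficit",
    "add_humidity_deficit",
    "daytime_mean",
    "daytime_mean_table",
    "pearson_correlation",
    "trailing_window_mean_T",
    "sensitivity_scan",
    "temp_at_fot",
    "drop_analysis",
    "group_compare",
]


class UndefinedCorrelation(ValueError):
    """Correlation undefined (zero variance or too few pairs)."""


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its two-sided t-based p-value."""

    r: float
    p: float
    n: int
    factor: str = ""
    window: str = ""


def humidity_deficit(T, H):
    """Humidity deficit in g/m^3 from air temperature (degC) and RH (%).

    The mass of water vapor per unit air volume needed to saturate the air:

        HD = 217/(T + 273.15) * 6.11 * 10^(7.5 T / (T + 237.3)) * (100 - H)/100

    combining the ideal-gas vapor density factor with the Tetens saturation
    vapor-pressure formula (hPa).  Vectorised over array inputs; zero at
    saturation (H = 100) by construction.
    """
    T = np.asarray(T, dtype=float)
    H = np.asarray(H, dtype=float)
    if np.any((H < 0) | (H > 100)):
        raise ValueError("relative humidity must be within [0, 100]")
    if np.any(T <= -100):
        raise ValueError("temperature below plausible range")
    sat = 6.11 * 10.0 ** (7.5 * T / (T + 237.3))
    hd = 217.0 / (T + 273.15) * sat * ((100.0 - H) / 100.0)
    return float(hd) if hd.ndim == 0 else hd


def add_humidity_deficit(weather: pd.DataFrame) -> pd.DataFrame:
    """Return the weather table with a derived ``hd`` column (g/m^3)."""
    out = weather.copy()
    out["hd"] = humidity_deficit(out["temp_c"].to_numpy(), out["rh_pct"].to_numpy())
    return out


def _hours(ts: pd.Series) -> np.ndarray:
    ts = pd.to_datetime(ts)
    return (ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0).to_numpy()


def daytime_mean(
    weather: pd.DataFrame,
    day: Date,
    channel: str = "temp_c",
    window: tuple[float, float] = (8.0, 15.0),
) -> tuple[float, int]:
    """Mean of one weather channel over a clock window on one date.

    The window is inclusive at both ends (default 8:00-15:00).  Returns
    ``(mean, n_records)``; an empty window yields ``(nan, 0)`` — missing,
    never imputed.
    """
    ts = pd.to_datetime(weather["timestamp"])
    hours = _hours(weather["timestamp"])
    mask = (ts.dt.date == day) & (hours >= window[0]) & (hours <= window[1])
    vals = weather.loc[mask.to_numpy(), channel].to_numpy(dtype=float)
    if vals.size == 0:
        return float("nan"), 0
    return float(vals.mean()), int(vals.size)


def daytime_mean_table(
    weather: pd.DataFrame,
    dates: Iterable[Date],
    channels: Sequence[str] = ("temp_c", "radiation", "rh_pct", "hd"),
    window: tuple[float, float] = (8.0, 15.0),
) -> pd.DataFrame:
    """Per-date daytime means of several channels (one row per date)."""
    rows = []
    for day in dates:
        row = {"date": day}
        for ch in channels:
            row[ch], _ = daytime_mean(weather, day, ch, window)
        rows.append(row)
    return pd.DataFrame(rows)


def pearson_correlation(
    x: Sequence[float], y: Sequence[float], factor: str = "", window: str = ""
) -> CorrelationResult:
    """Pearson r with two-sided p from t = r sqrt((n-2)/(1-r^2)), n-2 df.

    Pairs with a missing member are dropped; fewer than 3 complete pairs or
    zero variance raise :class:`UndefinedCorrelation`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise UndefinedCorrelation(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedCorrelation("zero variance in one of the variables")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), n, factor, window)


def trailing_window_mean_T(
    weather: pd.DataFrame,
    clock: datetime,
    span_min: int = 60,
    channel: str = "temp_c",
) -> float:
    """Mean of a channel over the right-closed window (clock-span, clock].

    On a clean 10-min grid with a 60-min span this averages 6 records.
    Returns NaN when no records fall inside the window.
    """
    ts = pd.to_datetime(weather["timestamp"])
    lo = clock - timedelta(minutes=span_min)
    mask = (ts > lo) & (ts <= clock)
    vals = weather.loc[mask.to_numpy(), channel].to_numpy(dtype=float)
    return float(vals.mean()) if vals.size else float("nan")


def sensitivity_scan(
    fot_by_date: Mapping[Date, float] | pd.Series,
    weather: pd.DataFrame,
    grid_min: int = 10,
    span_min: int = 60,
    start_hour: float = 0.0,
    end_hour: float = 24.0,
    min_n: int = 3,
) -> pd.DataFrame:
    """Correlate FOT with the trailing 1-h mean temperature at each clock time.

    For every clock time g on a ``grid_min``-minute grid, the trailing-window
    mean temperature ending at g is computed for each date with an FOT, and
    Pearson correlation is taken across dates.  Grid points with fewer than
    ``min_n`` complete dates are left missing.  Returns columns
    ``clock_hours, r, p, n``; the most negative r marks the temperature-
    sensitive phase.
    """
    if isinstance(fot_by_date, pd.Series):
        fot_by_date = fot_by_date.to_dict()
    dates = sorted(d for d, v in fot_by_date.items() if not pd.isna(v))
    fots = np.array([fot_by_date[d] for d in dates], dtype=float)

    ts = pd.to_datetime(weather["timestamp"])
    temp = weather["temp_c"].to_numpy(dtype=float)
    by_date: dict[Date, tuple[np.ndarray, np.ndarray]] = {}
    for d, grp in weather.groupby(ts.dt.date):
        h = _hours(grp["timestamp"])
        by_date[d] = (h, grp["temp_c"].to_numpy(dtype=float))

    grid = np.arange(start_hour * 60, end_hour * 60 + 1e-9, grid_min) / 60.0
    rows = []
    for g in grid:
        means = []
        for d in dates:
            if d not in by_date:
                means.append(np.nan)
                continue
            h, v = by_date[d]
            mask = (h > g - span_min / 60.0 + 1e-12) & (h <= g + 1e-12)
            means.append(v[mask].mean() if mask.any() else np.nan)
        means = np.asarray(means)
        ok = ~np.isnan(means)
        row = {"clock_hours": float(g), "r": np.nan, "p": np.nan, "n": int(ok.sum())}
        if ok.sum() >= min_n:
            try:
                res = pearson_correlation(means[ok], fots[ok])
                row.update(r=res.r, p=res.p)
            except UndefinedCorrelation:
                pass
        rows.append(row)
    return pd.DataFrame(rows)


def scan_argmin(scan: pd.DataFrame) -> tuple[float, float]:
    """Clock time (hours) and r of the strongest negative correlation."""
    valid = scan.dropna(subset=["r"])
    if len(valid) == 0:
        raise ValueError("sensitivity scan has no valid grid points")
    i = valid["r"].idxmin()
    return float(valid.loc[i, "clock_hours"]), float(valid.loc[i, "r"])


def temp_at_fot(weather: pd.DataFrame, day: Date, fot_hours: float) -> float:
    """Air temperature of the record nearest to the FOT (ties -> earlier).

    Returns NaN when the FOT falls outside the day's recorded span.
    """
    ts = pd.to_datetime(weather["timestamp"])
    mask = (ts.dt.date == day).to_numpy()
    if not mask.any():
        return float("nan")
    h = _hours(weather.loc[mask, "timestamp"])
    v = weather.loc[mask, "temp_c"].to_numpy(dtype=float)
    if fot_hours < h.min() - 1e-9 or fot_hours > h.max() + 1e-9:
        return float("nan")
    dist = np.abs(h - fot_hours)
    # stable argmin returns the first (earlier) record on exact ties
    return float(v[int(np.argmin(dist))])


@dataclass(frozen=True)
class DropAnalysis:
    """Fractions of days with a sharp temperature drop, by relative time.

    ``grid_min`` holds minutes relative to FOT; fractions are per day class
    (hot: daily max above the threshold; non-hot otherwise).
    """

    grid_min: np.ndarray
    frac_hot: np.ndarray
    frac_cool: np.ndarray
    n_hot: int
    n_cool: int
    hot_days: tuple[Date, ...]
    cool_days: tuple[Date, ...]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rel_min": self.grid_min,
                "frac_hot": self.frac_hot,
                "frac_cool": self.frac_cool,
                "n_hot": self.n_hot,
                "n_cool": self.n_cool,
            }
        )


def drop_analysis(
    weather: pd.DataFrame,
    fot_by_date: Mapping[Date, float] | pd.Series,
    drop_c: float = 0.5,
    hot_c: float = 35.0,
    grid_min: Sequence[int] = tuple(range(-120, 40, 10)),
) -> DropAnalysis:
    """Temperature-drop trigger statistics around the FOT.

    Days are classified hot when the full-day maximum temperature strictly
    exceeds ``hot_c``.  The FOT is aligned to the nearest weather record
    (ties -> earlier); at each relative offset rho the day counts as a drop
    day when the 10-min temperature difference at FOT+rho is strictly below
    ``-drop_c``.  Dates lacking an FOT or weather are skipped.
    """
    if isinstance(fot_by_date, pd.Series):
        fot_by_date = fot_by_date.to_dict()
    ts = pd.to_datetime(weather["timestamp"])
    grid = np.asarray(list(grid_min), dtype=int)

    hot_days: list[Date] = []
    cool_days: list[Date] = []
    hits = {}  # day -> bool array over grid
    for day, grp in weather.groupby(ts.dt.date):
        if day not in fot_by_date or pd.isna(fot_by_date[day]):
            continue
        h = _hours(grp["timestamp"])
        v = grp["temp_c"].to_numpy(dtype=float)
        is_hot = bool(v.max() > hot_c)
        fot = float(fot_by_date[day])
        anchor = int(np.argmin(np.abs(h - fot)))  # first index on ties
        # 10-min backward differences on the record grid
        delta = np.full_like(v, np.nan)
        delta[1:] = v[1:] - v[:-1]
        day_hits = np.zeros(len(grid), dtype=bool)
        for k, rho in enumerate(grid):
            j = anchor + rho // 10
            if 0 <= j < len(v) and not np.isnan(delta[j]):
                day_hits[k] = delta[j] < -drop_c
        hits[day] = day_hits
        (hot_days if is_hot else cool_days).append(day)

    def _frac(days: list[Date]) -> np.ndarray:
        if not days:
            return np.full(len(grid), np.nan)
        return np.mean([hits[d] for d in days], axis=0)

    return DropAnalysis(
        grid_min=grid,
        frac_hot=_frac(hot_days),
        frac_cool=_frac(cool_days),
        n_hot=len(hot_days),
        n_cool=len(cool_days),
        hot_days=tuple(hot_days),
        cool_days=tuple(cool_days),
    )


def group_compare(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests with Holm adjustment.

    Returns a symmetric p-value matrix with a unit diagonal (as used for
    boxplot letter displays).  Every group needs at least 2 observations.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for name, sample in groups.items():
        if len(sample) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    raw = []
    for a, b in pairs:
        stat = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        raw.append(stat.pvalue)
    adjusted = multipletests(raw, method="holm")[1] if raw else []
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for (a, b), p in zip(pairs, adjusted):
        mat.loc[a, b] = mat.loc[b, a] = float(min(p, 1.0))
    return mat
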