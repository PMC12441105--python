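"""Flower-index construction and daily flower-opening-time estimation.

The flower index at one frame time is the sum of the pixel heights of the
detection boxes that survived filtering on that side of the scene — a proxy
for the number of simultaneously open flowers (detected regions often hold
several flowers, so total height is more reliable than a raw box count).
The composite is split into a left and a right half (one cultivar each)
with a dead zone between them; a box belongs to the side containing its
center, and dead-zone boxes belong to neither.

Per calendar day and side, the index series is smoothed with a cubic
smoothing spline whose penalty is chosen by generalized cross-validation,
and the flower-opening time (FOT) is the clock time of the highest peak of
the smoothed curve on a 1-minute grid.  Days with fewer than 3 kept
detections are excluded rather than estimated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as Date
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.signal import argrelmax

__all__ = [
    "SideSplit",
    "FotEstimate",
    "InsufficientSupport",
    "assign_side",
    "assign_sides",
    "flower_index_series",
    "smooth_series",
    "estimate_fot",
    "estimate_fot_table",
    "fot_rmse",
    "neighboring_day_diff",
]

SIDES = ("left", "right")

#: Default exclusion rule: days with fewer kept detections than this have no
#: meaningful peak and are flagged instead of estimated.
MIN_DETECTIONS = 3


class InsufficientSupport(ValueError):
    """Too few distinct time points to fit a smoothing spline."""


@dataclass(frozen=True)
class SideSplit:
    """Left/right partition of the composite with a dead zone.

    Defaults match the usual four-pot layout (left: x < 1350, right:
    x > 1450); sessions with a different plant arrangement use 650/750.
    """

    left_max_x: float = 1350.0
    right_min_x: float = 1450.0

    def __post_init__(self) -> None:
        if not self.left_max_x < self.right_min_x:
            raise ValueError("left_max_x must be below right_min_x")


ALTERNATE_SPLIT = SideSplit(650.0, 750.0)


@dataclass(frozen=True)
class FotEstimate:
    """Daily FOT for one side of the scene."""

    date: Date
    side: str
    fot_est: float | None  # decimal hours; None when excluded
    peak_value: float
    n_detections: int
    excluded: bool
    secondary_peaks: tuple[tuple[float, float], ...] = ()
    gcv_lambda: float | None = None


def assign_side(center_x: float, split: SideSplit = SideSplit()) -> str:
    """Side of a box center: left, right, or none (dead zone)."""
    if center_x < split.left_max_x:
        return "left"
    if center_x > split.right_min_x:
        return "right"
    return "none"


def assign_sides(detections: pd.DataFrame, split: SideSplit = SideSplit()) -> pd.DataFrame:
    """Vectorised :func:`assign_side` over a detection table."""
    out = detections.copy()
    center = (out["x_min"].to_numpy(float) + out["x_max"].to_numpy(float)) / 2.0
    side = np.where(
        center < split.left_max_x, "left", np.where(center > split.right_min_x, "right", "none")
    )
    out["side"] = side
    return out


def flower_index_series(
    kept: pd.DataFrame,
    frame_timestamps: Sequence | pd.DatetimeIndex,
    split: SideSplit | None = None,
) -> pd.DataFrame:
    """Per-side flower index on the full frame grid.

    For every frame timestamp and side, the index is the sum of height_px of
    that side's kept boxes; frames with no boxes contribute index 0 so the
    diel series is complete.  If ``split`` is given, sides are (re)assigned
    from box centers first; otherwise the table's ``side`` column is used.
    Dead-zone boxes (side ``none``) enter neither series.

    Returns columns ``timestamp, side, index, n_boxes``.
    """
    if split is not None:
        kept = assign_sides(kept, split)
    grid = pd.DatetimeIndex(sorted(pd.to_datetime(frame_timestamps)))
    if grid.has_duplicates:
        raise ValueError("frame grid contains duplicate timestamps")
    frames = []
    for side in SIDES:
        sub = kept[kept["side"] == side]
        agg = (
            sub.groupby("timestamp")
            .agg(index=("height_px", "sum"), n_boxes=("height_px", "size"))
            .reindex(grid, fill_value=0)
        )
        agg.index.name = "timestamp"
        agg = agg.reset_index()
        agg["side"] = side
        frames.append(agg)
    out = pd.concat(frames, ignore_index=True)
    return out[["timestamp", "side", "index", "n_boxes"]]


def smooth_series(
    hours: np.ndarray, values: np.ndarray, lam: float | None = None
) -> tuple[Callable[[np.ndarray], np.ndarray], float | None]:
    """Cubic smoothing spline through (time-of-day, index) points.

    Minimises RSS + lam * integral(f'')^2 with ``lam`` chosen by generalized
    cross-validation when not given.  Returns ``(curve, lam)``.  Raises
    :class:`InsufficientSupport` below 4 distinct time points; callers fall
    back to the raw argmax.  A constant series short-circuits to a constant
    curve (GCV is degenerate there).
    """
    x = np.asarray(hours, dtype=float)
    y = np.asarray(values, dtype=float)
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    distinct = np.unique(x)
    if distinct.size < 4:
        raise InsufficientSupport(f"only {distinct.size} distinct time points")
    if np.ptp(y) == 0.0:
        c = float(y[0])
        return (lambda t: np.full_like(np.asarray(t, dtype=float), c)), None
    spline = make_smoothing_spline(x, y, lam=lam)
    chosen = lam
    if chosen is None:
        # recover the GCV-selected penalty for the audit trail
        chosen = getattr(spline, "lam", None)
    return spline, (float(chosen) if chosen is not None else None)


def _peaks_on_grid(grid: np.ndarray, curve_vals: np.ndarray, fraction: float):
    """Global argmax (earliest tie) plus interior local maxima above a
    fraction of the global peak."""
    peak_idx = int(np.argmax(curve_vals))  # argmax returns the first maximum
    peak_time = float(grid[peak_idx])
    peak_value = float(curve_vals[peak_idx])
    secondary = []
    if peak_value > 0:
        (locs,) = argrelmax(curve_vals)
        for i in locs:
            if i == peak_idx:
                continue
            if curve_vals[i] >= fraction * peak_value:
                secondary.append((float(grid[i]), float(curve_vals[i])))
    return peak_time, peak_value, tuple(secondary)


def estimate_fot(
    day_series: pd.DataFrame,
    n_detections: int | None = None,
    window: tuple[float, float] = (6.0, 18.0),
    min_detections: int = MIN_DETECTIONS,
    secondary_fraction: float = 0.25,
    lam: float | None = None,
) -> FotEstimate:
    """Estimate the FOT for one (date, side) from its index series.

    ``day_series`` needs columns ``timestamp, index, n_boxes`` for a single
    calendar date and side.  The smoothed curve is evaluated on a 1-minute
    grid restricted to ``window`` intersected with the day's observation
    span; the FOT is the time of the highest peak (ties broken earliest).
    Local maxima above ``secondary_fraction`` of the global peak are
    reported as secondary peaks (split flowering events).  Exclusion for
    fewer than ``min_detections`` kept boxes is a value, not an error.
    """
    ts = pd.to_datetime(day_series["timestamp"])
    dates = ts.dt.date.unique()
    if len(dates) != 1:
        raise ValueError(f"day_series spans {len(dates)} dates; expected exactly 1")
    day = dates[0]
    side = day_series["side"].iloc[0] if "side" in day_series.columns else "none"
    if n_detections is None:
        n_detections = int(day_series["n_boxes"].sum())

    if n_detections < min_detections:
        return FotEstimate(day, side, None, 0.0, n_detections, excluded=True)

    hours = (ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0).to_numpy()
    values = day_series["index"].to_numpy(dtype=float)
    lo = max(window[0], float(hours.min()))
    hi = min(window[1], float(hours.max()))
    if not lo < hi:
        lo, hi = float(hours.min()), float(hours.max())
    grid = np.arange(math.ceil(lo * 60), math.floor(hi * 60) + 1) / 60.0

    try:
        curve, chosen_lam = smooth_series(hours, values, lam=lam)
        curve_vals = np.asarray(curve(grid), dtype=float)
    except InsufficientSupport:
        # raw argmax fallback for sparse days that still pass the count rule
        in_win = (hours >= lo) & (hours <= hi)
        idx = int(np.argmax(values[in_win]))
        t = float(hours[in_win][idx])
        return FotEstimate(day, side, t, float(values[in_win][idx]), n_detections, False)

    peak_time, peak_value, secondary = _peaks_on_grid(grid, curve_vals, secondary_fraction)
    return FotEstimate(
        day,
        side,
        peak_time,
        peak_value,
        n_detections,
        excluded=False,
        secondary_peaks=secondary,
        gcv_lambda=chosen_lam,
    )


def estimate_fot_table(
    index_series: pd.DataFrame,
    window: tuple[float, float] = (6.0, 18.0),
    min_detections: int = MIN_DETECTIONS,
    secondary_fraction: float = 0.25,
) -> pd.DataFrame:
    """Run :func:`estimate_fot` over every (date, side) of an index series.

    Returns columns ``date, side, fot_est, peak_value, n_detections,
    excluded, secondary_peaks, gcv_lambda`` with ``fot_est`` in decimal
    hours (NaN when excluded).
    """
    df = index_series.copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.date
    rows = []
    for (day, side), grp in df.groupby(["date", "side"], sort=True):
        est = estimate_fot(
            grp,
            window=window,
            min_detections=min_detections,
            secondary_fraction=secondary_fraction,
        )
        rows.append(
            {
                "date": day,
                "side": side,
                "fot_est": np.nan if est.fot_est is None else est.fot_est,
                "peak_value": est.peak_value,
                "n_detections": est.n_detections,
                "excluded": est.excluded,
                "secondary_peaks": ";".join(f"{t:.4f}@{v:.2f}" for t, v in est.secondary_peaks),
                "gcv_lambda": np.nan if est.gcv_lambda is None else est.gcv_lambda,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "date",
            "side",
            "fot_est",
            "peak_value",
            "n_detections",
            "excluded",
            "secondary_peaks",
            "gcv_lambda",
        ],
    )


@dataclass(frozen=True)
class FotValidation:
    rmse_h: float
    mean_error_h: float
    n: int


def fot_rmse(estimates: pd.DataFrame, observed: pd.DataFrame) -> FotValidation:
    """RMSE of estimated vs observed FOT in hours.

    Joined on (date, side); excluded days are dropped.  Also reports the
    mean signed error (estimate minus observation) and the pair count.
    """
    est = estimates.loc[~estimates["excluded"], ["date", "side", "fot_est"]]
    merged = est.merge(observed[["date", "side", "fot_observed"]], on=["date", "side"])
    if len(merged) == 0:
        raise ValueError("no overlapping (date, side) pairs between estimates and observations")
    err = merged["fot_est"].to_numpy(float) - merged["fot_observed"].to_numpy(float)
    return FotValidation(
        rmse_h=float(np.sqrt(np.mean(err**2))),
        mean_error_h=float(np.mean(err)),
        n=len(merged),
    )


def neighboring_day_diff(estimates: pd.DataFrame, side: str | None = None):
    """Mean +/- SD (minutes) of |FOT difference| between consecutive days.

    Only date pairs exactly one day apart, both with non-excluded estimates,
    are counted; SD uses the n-1 denominator.  Returns ``(mean, sd, n)``.
    """
    df = estimates.loc[~estimates["excluded"]]
    if side is not None:
        df = df[df["side"] == side]
    df = df.sort_values("date")
    diffs = []
    for _, grp in df.groupby("side"):
        dates = pd.to_datetime(pd.Series(grp["date"].to_numpy()))
        fots = grp["fot_est"].to_numpy(float)
        step = dates.diff().dt.days.to_numpy()
        for i in np.flatnonzero(step == 1):
            diffs.append(abs(fots[i] - fots[i - 1]) * 60.0)
    if not diffs:
        raise ValueError("no consecutive-day estimate pairs")
    arr = np.asarray(diffs)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd, len(arr)
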