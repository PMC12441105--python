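"""Synthetic study generator with complete ground truth.

Emulates the monitoring campaign at every stage so the whole pipeline can be
exercised against known answers:

* diel weather series (temperature sinusoid peaking mid-afternoon plus AR(1)
  noise, humidity anti-phased, radiation a daylight half-sine) with
  optionally injected transient temperature dips;
* detection streams: per day and scene side, flower boxes whose appearance
  times cluster Gaussian around a configurable true flower-opening time,
  plus labeled false positives (dark shadow-like boxes and low-score boxes)
  that the downstream filter should remove;
* rendered 2800x2800 composite frames — dark backdrop, filled yellow
  rectangles for flowers, dark bluish rectangles for shadows — on which the
  mock detector recovers the planted geometry.

Every stage is a deterministic function of (config, seed), and everything an
assertion could need (true FOTs, planted boxes, dip events, day classes) is
recorded in the returned truth objects rather than re-derived from images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as Date, datetime, time, timedelta
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .filterchain import DETECTION_COLUMNS
from .fot_estimator import SideSplit

__all__ = [
    "WeatherConfig",
    "SceneConfig",
    "WeatherTruth",
    "DetectionTruth",
    "generate_weather",
    "generate_detections",
    "render_frames",
    "render_composite",
    "frame_grid",
    "PANICLE_RGB",
    "SHADOW_RGB",
    "BACKDROP_RGB",
]

# Scene palette.  The backdrop emulates the black cloth behind the plants
# (near-neutral, encoded b ~ 127); panicles are saturated yellow (b >> 140);
# shadow confounders are dark and bluish (b < 140) so the color filter is
# discriminative by construction.
BACKDROP_RGB = (28, 30, 33)
PANICLE_RGB = (235, 200, 70)
SHADOW_RGB = (45, 48, 80)


@dataclass(frozen=True)
class WeatherConfig:
    """Parameters of the simulated diel weather.

    ``daily_mean_t`` maps each date to its mean temperature (degC); the diel
    cycle is ``mean + amplitude * cos(2 pi (h - peak_hour)/24)`` so the
    daily maximum is roughly mean + amplitude at ``peak_hour``.  AR(1) noise
    (coefficient 0.8 at the 10-min lag, innovation SD ``noise_sd``) keeps
    traces smooth enough not to trip the 0.5 degC drop rule spuriously.
    ``dips`` lists (timestamp, magnitude degC) transient drops: the single
    record at that timestamp is lowered by the magnitude.
    """

    daily_mean_t: Mapping[Date, float]
    amplitude_c: float = 4.0
    peak_hour: float = 14.0
    ar_coeff: float = 0.8
    noise_sd: float = 0.08
    cadence_min: int = 10
    base_rh: float = 70.0
    rh_amplitude: float = 15.0
    radiation_max: float = 800.0
    dips: Sequence[tuple[datetime, float]] = ()


@dataclass(frozen=True)
class WeatherTruth:
    """Ground truth for a generated weather series."""

    daily_mean_t: dict[Date, float]
    daytime_mean_t: dict[Date, float]  # realized mean over 8:00-15:00
    daily_max_t: dict[Date, float]
    hot_days: tuple[Date, ...]  # daily max strictly above 35 degC
    dips: tuple[tuple[datetime, float], ...]
    seed: int


def generate_weather(cfg: WeatherConfig, seed: int) -> tuple[pd.DataFrame, WeatherTruth]:
    """Simulate a 10-min-cadence weather table over the configured dates."""
    rng = np.random.default_rng(seed)
    dates = sorted(cfg.daily_mean_t)
    steps_per_day = 24 * 60 // cfg.cadence_min
    timestamps, temps, rhs, rads = [], [], [], []
    noise = 0.0
    innov_sd = cfg.noise_sd * math.sqrt(max(1e-12, 1 - cfg.ar_coeff**2))
    for day in dates:
        mean_t = cfg.daily_mean_t[day]
        for k in range(steps_per_day):
            minutes = k * cfg.cadence_min
            h = minutes / 60.0
            ts = datetime.combine(day, time(0, 0)) + timedelta(minutes=minutes)
            diel = math.cos(2 * math.pi * (h - cfg.peak_hour) / 24.0)
            noise = cfg.ar_coeff * noise + rng.normal(0.0, innov_sd)
            temps.append(mean_t + cfg.amplitude_c * diel + noise)
            rhs.append(
                float(np.clip(cfg.base_rh - cfg.rh_amplitude * diel + rng.normal(0, 0.5), 1, 99))
            )
            rads.append(max(0.0, cfg.radiation_max * math.sin(math.pi * (h - 6.0) / 12.0)))
            timestamps.append(ts)
    df = pd.DataFrame(
        {"timestamp": timestamps, "temp_c": temps, "rh_pct": rhs, "radiation": rads}
    )
    for ts, mag in cfg.dips:
        idx = df.index[df["timestamp"] == pd.Timestamp(ts)]
        if len(idx) == 0:
            raise ValueError(f"dip timestamp {ts} not on the weather grid")
        df.loc[idx, "temp_c"] -= mag

    tsd = pd.to_datetime(df["timestamp"]).dt
    hours = tsd.hour + tsd.minute / 60.0
    daytime = {}
    daymax = {}
    for day, grp in df.groupby(tsd.date):
        sel = (hours >= 8.0) & (hours <= 15.0) & (tsd.date == day)
        daytime[day] = float(df.loc[sel.to_numpy(), "temp_c"].mean())
        daymax[day] = float(grp["temp_c"].max())
    hot = tuple(d for d in dates if daymax[d] > 35.0)
    truth = WeatherTruth(
        daily_mean_t=dict(cfg.daily_mean_t),
        daytime_mean_t=daytime,
        daily_max_t=daymax,
        hot_days=hot,
        dips=tuple(cfg.dips),
        seed=seed,
    )
    return df, truth


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the simulated detection stream / rendered scenes.

    ``fot_profile`` maps (date, side) to the true flower-opening time in
    decimal hours.  Per day and side, the number of flowers is Poisson
    (``flowers_per_day_mean``, overridable per date) and each flower's
    appearance time is Gaussian around the true FOT with SD
    ``fot_sigma_min`` minutes, snapped to the frame grid.  Box sizes are
    bounded so true-flower areas stay below the 6000 px filter cut.
    """

    fot_profile: Mapping[tuple[Date, str], float]
    frame_start: float = 6.0
    frame_end: float = 18.0
    frame_interval_min: int = 10
    flowers_per_day_mean: float = 15.0
    flowers_per_day_override: Mapping[Date, int] = field(default_factory=dict)
    fot_sigma_min: float = 20.0
    width_range: tuple[int, int] = (40, 85)
    height_range: tuple[int, int] = (30, 70)
    shadow_rate_per_day: float = 0.0
    lowscore_rate_per_day: float = 0.0
    split: SideSplit = SideSplit()
    margin_px: int = 60


@dataclass(frozen=True)
class DetectionTruth:
    """Ground truth for a generated detection stream."""

    fot_true: dict[tuple[Date, str], float]
    n_true: dict[tuple[Date, str], int]
    n_false: int
    seed: int


def frame_grid(cfg: SceneConfig, dates: Sequence[Date]) -> pd.DatetimeIndex:
    """All frame timestamps of the campaign (camera window, 10-min steps)."""
    out = []
    start = int(round(cfg.frame_start * 60))
    end = int(round(cfg.frame_end * 60))
    for day in dates:
        for minutes in range(start, end + 1, cfg.frame_interval_min):
            out.append(datetime.combine(day, time(0, 0)) + timedelta(minutes=minutes))
    return pd.DatetimeIndex(out)


def _snap_to_grid(hours: float, cfg: SceneConfig) -> float:
    step = cfg.frame_interval_min / 60.0
    snapped = round((hours - cfg.frame_start) / step) * step + cfg.frame_start
    return float(min(max(snapped, cfg.frame_start), cfg.frame_end))


def _side_x_range(side: str, cfg: SceneConfig, width: int) -> tuple[int, int]:
    if side == "left":
        lo, hi = cfg.margin_px, int(cfg.split.left_max_x) - cfg.margin_px - width
    else:
        lo, hi = int(cfg.split.right_min_x) + cfg.margin_px, 2800 - cfg.margin_px - width
    return lo, max(lo + 1, hi)


def _place_box(rng, cfg: SceneConfig, side: str, occupied: list) -> tuple[int, int, int, int]:
    """Rejection-sample a box on the given side avoiding overlap (50 tries)."""
    for _ in range(50):
        w = int(rng.integers(cfg.width_range[0], cfg.width_range[1] + 1))
        h = int(rng.integers(cfg.height_range[0], cfg.height_range[1] + 1))
        lo, hi = _side_x_range(side, cfg, w)
        x0 = int(rng.integers(lo, hi))
        y0 = int(rng.integers(cfg.margin_px, 2800 - cfg.margin_px - h))
        box = (x0, y0, x0 + w, y0 + h)
        pad = 12
        if all(
            box[2] + pad <= o[0] or o[2] + pad <= box[0] or box[3] + pad <= o[1] or o[3] + pad <= box[1]
            for o in occupied
        ):
            occupied.append(box)
            return box
    occupied.append(box)
    return box  # crowded frame: accept the overlap


def generate_detections(
    cfg: SceneConfig, seed: int
) -> tuple[pd.DataFrame, DetectionTruth]:
    """Simulate the post-detector stream (before filtering), with truth.

    True flowers carry scores in (0.75, 0.99), mean b around 205 and areas
    under the 6000 px cut, so a zero-false-positive stream passes the filter
    in full.  Shadow confounders copy the score range but sit near b = 120;
    low-score confounders are yellow but score in (0.5, 0.7).  The
    ``is_true`` column labels the classes for oracle tests; strip it to get
    the canonical schema.
    """
    rng = np.random.default_rng(seed)
    dates = sorted({d for d, _ in cfg.fot_profile})
    rows = []
    n_true: dict[tuple[Date, str], int] = {}
    n_false = 0
    occupied_by_ts: dict[datetime, list] = {}
    for day in dates:
        for side in ("left", "right"):
            key = (day, side)
            if key not in cfg.fot_profile:
                continue
            fot = cfg.fot_profile[key]
            if day in cfg.flowers_per_day_override:
                n = int(cfg.flowers_per_day_override[day])
            else:
                n = int(rng.poisson(cfg.flowers_per_day_mean))
            n_true[key] = n
            for _ in range(n):
                t = _snap_to_grid(fot + rng.normal(0.0, cfg.fot_sigma_min) / 60.0, cfg)
                ts = datetime.combine(day, time(0, 0)) + timedelta(minutes=round(t * 60))
                occ = occupied_by_ts.setdefault(ts, [])
                x0, y0, x1, y1 = _place_box(rng, cfg, side, occ)
                rows.append(
                    {
                        "timestamp": ts,
                        "x_min": x0,
                        "y_min": y0,
                        "x_max": x1,
                        "y_max": y1,
                        "score": float(rng.uniform(0.75, 0.99)),
                        "mean_b": float(np.clip(rng.normal(205.0, 10.0), 160.0, 250.0)),
                        "area_px": (x1 - x0) * (y1 - y0),
                        "height_px": y1 - y0,
                        "side": side,
                        "is_true": True,
                    }
                )
        # confounders are spread over the whole camera window
        grid = frame_grid(cfg, [day])
        for rate, kind in ((cfg.shadow_rate_per_day, "shadow"), (cfg.lowscore_rate_per_day, "lowscore")):
            for _ in range(int(rng.poisson(rate))):
                ts = grid[int(rng.integers(0, len(grid)))].to_pydatetime()
                side = "left" if rng.random() < 0.5 else "right"
                occ = occupied_by_ts.setdefault(ts, [])
                x0, y0, x1, y1 = _place_box(rng, cfg, side, occ)
                if kind == "shadow":
                    score = float(rng.uniform(0.75, 0.99))
                    mb = float(np.clip(rng.normal(120.0, 5.0), 100.0, 135.0))
                else:
                    score = float(rng.uniform(0.5, 0.699))
                    mb = float(np.clip(rng.normal(205.0, 10.0), 160.0, 250.0))
                rows.append(
                    {
                        "timestamp": ts,
                        "x_min": x0,
                        "y_min": y0,
                        "x_max": x1,
                        "y_max": y1,
                        "score": score,
                        "mean_b": mb,
                        "area_px": (x1 - x0) * (y1 - y0),
                        "height_px": y1 - y0,
                        "side": side,
                        "is_true": False,
                    }
                )
                n_false += 1
    df = pd.DataFrame(rows, columns=DETECTION_COLUMNS + ["is_true"])
    if len(df):
        df = df.sort_values(["timestamp", "x_min", "y_min"], kind="mergesort").reset_index(
            drop=True
        )
    truth = DetectionTruth(
        fot_true=dict(cfg.fot_profile), n_true=n_true, n_false=n_false, seed=seed
    )
    return df, truth


def render_composite(detections_at_ts: pd.DataFrame) -> np.ndarray:
    """Render one 2800x2800 composite for the boxes of a single timestamp.

    True-class boxes are drawn panicle yellow, false-class boxes shadow
    colored (an ``is_true`` column is required; rendering is about giving
    the mock detector the right colors to find).
    """
    img = np.empty((2800, 2800, 3), dtype=np.uint8)
    img[:] = BACKDROP_RGB
    for r in detections_at_ts.itertuples(index=False):
        color = PANICLE_RGB if getattr(r, "is_true", True) else SHADOW_RGB
        img[int(r.y_min) : int(r.y_max), int(r.x_min) : int(r.x_max)] = color
    return img


def render_frames(
    cfg: SceneConfig,
    detections: pd.DataFrame,
    frame_size: tuple[int, int] | None = None,
    roi_origin: tuple[int, int] = (0, 0),
) -> Iterator[tuple[datetime, np.ndarray]]:
    """Yield (timestamp, frame) pairs for every frame of the campaign.

    Frames are generated lazily (a composite is 23 MB).  With ``frame_size``
    given (width, height), the composite is embedded in a backdrop-colored
    raw canvas at ``roi_origin``, emulating the full camera frame.
    """
    dates = sorted({d for d, _ in cfg.fot_profile})
    det = detections.copy()
    det["timestamp"] = pd.to_datetime(det["timestamp"])
    for ts in frame_grid(cfg, dates):
        comp = render_composite(det[det["timestamp"] == ts])
        if frame_size is None:
            yield ts.to_pydatetime(), comp
        else:
            w, h = frame_size
            canvas = np.empty((h, w, 3), dtype=np.uint8)
            canvas[:] = BACKDROP_RGB
            ox, oy = roi_origin
            canvas[oy : oy + 2800, ox : ox + 2800] = comp
            yield ts.to_pydatetime(), canvas
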