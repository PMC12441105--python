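"""False-positive filtering of flower detections.

A detector run on tiled greenhouse imagery fires both on open rice flowers
(yellow, compact) and on confounders such as shadows of blackout nets (dark,
bluish) or large glare patches.  Correct flowering regions overlap mature
panicles, which appear yellow, so they separate cleanly from confounders in
the blue-yellow (b) axis of CIE L*a*b* and in box area.  This module computes
the per-box color feature and applies the three-way filter

    score > 0.7   AND   mean b > 140   AND   area < 6000 px

with all inequalities strict.  The b channel uses the common 8-bit offset
encoding (b_enc = b* + 128, clamped to [0, 255]) so the neutral axis maps to
128 and saturated yellow well above 140.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage.color import rgb2lab

__all__ = [
    "DetectionRecord",
    "FilterThresholds",
    "DETECTION_COLUMNS",
    "srgb_to_b_enc",
    "mean_b",
    "annotate_mean_b",
    "apply_filters",
    "records_to_frame",
    "frame_to_records",
]

#: Column schema of a detection table (composite pixels, 0-based, half-open).
DETECTION_COLUMNS = [
    "timestamp",
    "x_min",
    "y_min",
    "x_max",
    "y_max",
    "score",
    "mean_b",
    "area_px",
    "height_px",
    "side",
]

SIDES = ("left", "right", "none")


@dataclass(frozen=True)
class DetectionRecord:
    """One detector box in composite coordinates.

    Coordinates are 0-based, half-open ``[min, max)`` so that
    ``area_px == (x_max - x_min) * (y_max - y_min)`` exactly; area and height
    are derived properties and therefore consistent by construction.
    """

    timestamp: datetime
    x_min: int
    y_min: int
    x_max: int
    y_max: int
    score: float
    mean_b: float = float("nan")
    side: str = "none"

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box ({self.x_min},{self.y_min},{self.x_max},{self.y_max})"
            )
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")

    @property
    def width_px(self) -> int:
        return self.x_max - self.x_min

    @property
    def height_px(self) -> int:
        return self.y_max - self.y_min

    @property
    def area_px(self) -> int:
        return self.width_px * self.height_px

    @property
    def center_x(self) -> float:
        return (self.x_min + self.x_max) / 2.0


@dataclass(frozen=True)
class FilterThresholds:
    """Hand-tuned thresholds separating flowers from false positives.

    Defaults are the operational values: confidence score strictly above 0.7,
    mean 8-bit Lab b strictly above 140, box area strictly below 6000 px.
    """

    score_min: float = 0.7
    b_min: float = 140.0
    area_max: int = 6000

    def __post_init__(self) -> None:
        if not 0.0 < self.score_min <= 1.0:
            raise ValueError("score_min must be in (0, 1]")
        if not 0.0 <= self.b_min <= 255.0:
            raise ValueError("b_min must be in [0, 255]")
        if self.area_max <= 0:
            raise ValueError("area_max must be positive")


def records_to_frame(records: Iterable[DetectionRecord]) -> pd.DataFrame:
    """Convert DetectionRecords to the canonical detection DataFrame."""
    rows = [
        {
            "timestamp": r.timestamp,
            "x_min": r.x_min,
            "y_min": r.y_min,
            "x_max": r.x_max,
            "y_max": r.y_max,
            "score": r.score,
            "mean_b": r.mean_b,
            "area_px": r.area_px,
            "height_px": r.height_px,
            "side": r.side,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
    if len(df):
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def frame_to_records(df: pd.DataFrame) -> list[DetectionRecord]:
    return [
        DetectionRecord(
            timestamp=row.timestamp.to_pydatetime()
            if isinstance(row.timestamp, pd.Timestamp)
            else row.timestamp,
            x_min=int(row.x_min),
            y_min=int(row.y_min),
            x_max=int(row.x_max),
            y_max=int(row.y_max),
            score=float(row.score),
            mean_b=float(row.mean_b),
            side=str(row.side),
        )
        for row in df.itertuples(index=False)
    ]


def srgb_to_b_enc(image: np.ndarray) -> np.ndarray:
    """8-bit-encoded b channel of CIE L*a*b* (D65) for an sRGB image.

    ``b_enc = clamp(b* + 128, 0, 255)``: neutral pixels map to 128, yellow
    above, blue below.  Accepts uint8 or float images in [0, 1].
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an RGB image (H, W, 3), got shape {img.shape}")
    lab = rgb2lab(img)
    return np.clip(lab[..., 2] + 128.0, 0.0, 255.0)


def mean_b(image: np.ndarray, box: tuple[int, int, int, int]) -> float:
    """Mean encoded-b over a box of a composite sRGB image.

    ``box`` is ``(x_min, y_min, x_max, y_max)``, 0-based half-open, and must
    lie inside the image.
    """
    x_min, y_min, x_max, y_max = (int(v) for v in box)
    h, w = image.shape[:2]
    if not (0 <= x_min < x_max <= w and 0 <= y_min < y_max <= h):
        raise ValueError(f"box {box} outside image of size {w}x{h} or degenerate")
    patch = image[y_min:y_max, x_min:x_max]
    return float(srgb_to_b_enc(patch).mean())


def annotate_mean_b(detections: pd.DataFrame, composite: np.ndarray) -> pd.DataFrame:
    """Fill the mean_b column of a detection table from a composite image."""
    out = detections.copy()
    out["mean_b"] = [
        mean_b(composite, (r.x_min, r.y_min, r.x_max, r.y_max))
        for r in out.itertuples(index=False)
    ]
    return out


def apply_filters(
    detections: pd.DataFrame, thresholds: FilterThresholds = FilterThresholds()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split detections into kept and rejected per the three strict criteria.

    Returns ``(kept, rejected)``; ``rejected`` carries a ``reject_reasons``
    column listing every failed criterion (comma-joined among
    ``score``, ``b``, ``area``).  Total function: never raises on valid
    tables, and ``len(kept) + len(rejected) == len(detections)``.
    """
    df = detections
    missing = [c for c in ("score", "mean_b", "area_px") if c not in df.columns]
    if missing:
        raise ValueError(f"detection table lacks columns {missing}")

    score_ok = df["score"].to_numpy(dtype=float) > thresholds.score_min
    b_ok = df["mean_b"].to_numpy(dtype=float) > thresholds.b_min
    area_ok = df["area_px"].to_numpy(dtype=float) < thresholds.area_max
    keep = score_ok & b_ok & area_ok

    kept = df.loc[keep].copy()
    rejected = df.loc[~keep].copy()
    reasons = []
    for s, b, a in zip(score_ok[~keep], b_ok[~keep], area_ok[~keep]):
        failed = []
        if not s:
            failed.append("score")
        if not b:
            failed.append("b")
        if not a:
            failed.append("area")
        reasons.append(",".join(failed))
    rejected["reject_reasons"] = reasons
    return kept, rejected
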