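"""Composite cropping, 4x4 tiling and detector-box remapping.

The camera records 4608x3456 frames; analysis uses a fixed 2800x2800 region
containing the monitored plants.  That composite is partitioned into 16
disjoint tiles of 700x700 which are resized to the detector's 640x640 input;
detector boxes come back in model space and are mapped to composite
coordinates by the exact rational factor 700/640 plus the tile offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "COMPOSITE_SIZE",
    "TILE_SIZE",
    "GRID",
    "MODEL_INPUT",
    "CompositeRoi",
    "TileSpec",
    "RawBox",
    "tile_specs",
    "crop_composite",
    "tile_composite",
    "reassemble",
    "box_to_composite",
    "centered_roi",
]

COMPOSITE_SIZE = 2800
TILE_SIZE = 700
GRID = 4  # 4x4 -> 16 tiles
MODEL_INPUT = 640


@dataclass(frozen=True)
class CompositeRoi:
    """Origin of the 2800x2800 analysis region inside a raw frame."""

    origin_x: int
    origin_y: int
    size: int = COMPOSITE_SIZE

    def __post_init__(self) -> None:
        if self.origin_x < 0 or self.origin_y < 0:
            raise ValueError("ROI origin must be non-negative")


def centered_roi(frame_width: int, frame_height: int, size: int = COMPOSITE_SIZE) -> CompositeRoi:
    """Default ROI: the composite centered in the raw frame."""
    if frame_width < size or frame_height < size:
        raise ValueError(
            f"frame {frame_width}x{frame_height} smaller than composite size {size}"
        )
    return CompositeRoi((frame_width - size) // 2, (frame_height - size) // 2, size)


@dataclass(frozen=True)
class TileSpec:
    """One of the 16 tiles: grid position and geometry."""

    row: int
    col: int
    tile_size: int = TILE_SIZE
    model_input: int = MODEL_INPUT

    def __post_init__(self) -> None:
        if not (0 <= self.row < GRID and 0 <= self.col < GRID):
            raise ValueError(f"tile position ({self.row},{self.col}) outside 0..{GRID - 1}")

    @property
    def offset_x(self) -> int:
        return self.col * self.tile_size

    @property
    def offset_y(self) -> int:
        return self.row * self.tile_size


@dataclass(frozen=True)
class RawBox:
    """Detector output box in 640x640 model space, attached to its tile."""

    tile: TileSpec
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    score: float

    def __post_init__(self) -> None:
        m = self.tile.model_input
        if not (0 <= self.x_min < self.x_max <= m and 0 <= self.y_min < self.y_max <= m):
            raise ValueError(
                f"box ({self.x_min},{self.y_min},{self.x_max},{self.y_max}) "
                f"outside model space [0,{m}] or degenerate"
            )
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")


def tile_specs() -> list[TileSpec]:
    """The 16 tile specs in row-major order."""
    return [TileSpec(r, c) for r in range(GRID) for c in range(GRID)]


def crop_composite(frame: np.ndarray, roi: CompositeRoi) -> np.ndarray:
    """Extract the ROI; raises if the ROI does not fit inside the frame."""
    h, w = frame.shape[:2]
    if roi.origin_x + roi.size > w or roi.origin_y + roi.size > h:
        raise ValueError(
            f"ROI origin ({roi.origin_x},{roi.origin_y}) + size {roi.size} "
            f"exceeds frame {w}x{h}"
        )
    return frame[roi.origin_y : roi.origin_y + roi.size, roi.origin_x : roi.origin_x + roi.size]


def tile_composite(composite: np.ndarray) -> list[tuple[TileSpec, np.ndarray]]:
    """Partition a 2800x2800 image into 16 disjoint 700x700 tiles."""
    h, w = composite.shape[:2]
    if h != COMPOSITE_SIZE or w != COMPOSITE_SIZE:
        raise ValueError(f"expected a {COMPOSITE_SIZE}x{COMPOSITE_SIZE} composite, got {w}x{h}")
    out = []
    for spec in tile_specs():
        tile = composite[
            spec.offset_y : spec.offset_y + spec.tile_size,
            spec.offset_x : spec.offset_x + spec.tile_size,
        ]
        out.append((spec, tile))
    return out


def reassemble(tiles: list[tuple[TileSpec, np.ndarray]]) -> np.ndarray:
    """Inverse of :func:`tile_composite`; bit-exact round trip."""
    if len(tiles) != GRID * GRID:
        raise ValueError(f"expected {GRID * GRID} tiles, got {len(tiles)}")
    sample = tiles[0][1]
    shape = (COMPOSITE_SIZE, COMPOSITE_SIZE) + sample.shape[2:]
    out = np.empty(shape, dtype=sample.dtype)
    seen = set()
    for spec, tile in tiles:
        if (spec.row, spec.col) in seen:
            raise ValueError(f"duplicate tile ({spec.row},{spec.col})")
        seen.add((spec.row, spec.col))
        out[
            spec.offset_y : spec.offset_y + spec.tile_size,
            spec.offset_x : spec.offset_x + spec.tile_size,
        ] = tile
    return out


def _round_half_away(x: float) -> int:
    # round-half-away-from-zero; coordinates here are always >= 0
    return int(np.floor(x + 0.5)) if x >= 0 else int(np.ceil(x - 0.5))


def box_to_composite(box: RawBox) -> tuple[int, int, int, int] | None:
    """Map a model-space box into composite pixels.

    Scales by tile_size/model_input (700/640), rounds half-away-from-zero,
    offsets by the tile origin and clips to the composite.  Returns ``None``
    for boxes that collapse to zero width or height after rounding.
    """
    t = box.tile
    scale = t.tile_size / t.model_input
    x_min = _round_half_away(box.x_min * scale) + t.offset_x
    x_max = _round_half_away(box.x_max * scale) + t.offset_x
    y_min = _round_half_away(box.y_min * scale) + t.offset_y
    y_max = _round_half_away(box.y_max * scale) + t.offset_y
    x_min = max(0, min(x_min, COMPOSITE_SIZE))
    x_max = max(0, min(x_max, COMPOSITE_SIZE))
    y_min = max(0, min(y_min, COMPOSITE_SIZE))
    y_max = max(0, min(y_max, COMPOSITE_SIZE))
    if x_min >= x_max or y_min >= y_max:
        return None
    return (x_min, y_min, x_max, y_max)
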