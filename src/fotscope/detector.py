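"""Detector contract and implementations.

The contract is: a 700x700 RGB tile goes in, boxes with confidence scores in
640x640 model space come out.  Two implementations are provided:

* :class:`MockDetector` — a deterministic, pure function of the tile
  content used throughout the test suite.  It finds connected components
  that deviate from the tile's background color and emits one box per
  component, scoring yellow (high Lab b) components higher than dark ones.
  This exercises the geometry and color-filter paths on synthetic scenes
  without any learned model.
* :class:`OnnxDetector` — an adapter that runs an externally supplied
  object-detection model file through onnxruntime (an optional extra).

Both honour ``score_floor``: boxes below the floor are dropped before any
downstream filtering (a coarse first pass ahead of the stricter 0.7 cut).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.measure import label, regionprops

from . import tiler
from .filterchain import DETECTION_COLUMNS, annotate_mean_b, srgb_to_b_enc
from .tiler import CompositeRoi, RawBox, TileSpec

__all__ = ["DetectorConfig", "DetectorError", "MockDetector", "OnnxDetector", "detect_tile", "detect_frame"]


class DetectorError(RuntimeError):
    """Model could not be loaded or run."""


@dataclass(frozen=True)
class DetectorConfig:
    """Shared detector settings.

    ``score_floor`` is the coarse pre-filter (default 0.5); it must not
    exceed the strict downstream score threshold or kept-set accounting
    breaks.
    """

    model_path: str | None = None
    score_floor: float = 0.5
    input_size: int = tiler.MODEL_INPUT

    def __post_init__(self) -> None:
        if not 0.0 <= self.score_floor <= 1.0:
            raise ValueError("score_floor must be in [0, 1]")


@dataclass(frozen=True)
class MockDetector:
    """Connected-component detector over background-deviating pixels.

    Pixels whose L1 RGB distance from the tile's median color exceeds
    ``color_distance`` are foreground; each connected component of at least
    ``min_area_px`` tile pixels yields one box.  Components whose mean
    encoded Lab b exceeds ``b_split`` (yellow, flower-like) score
    ``score_bright``; the rest (shadow-like) score ``score_dark``.  Pure
    function of (tile, parameters): identical tiles give identical boxes.
    """

    color_distance: float = 60.0
    min_area_px: int = 40
    score_bright: float = 0.9
    score_dark: float = 0.85
    b_split: float = 140.0

    def __call__(self, tile: np.ndarray) -> list[tuple[float, float, float, float, float]]:
        """Boxes ``(x_min, y_min, x_max, y_max, score)`` in tile (700px) space."""
        _check_rgb(tile)
        img = tile.astype(np.int32)
        median = np.median(img.reshape(-1, 3), axis=0)
        dist = np.abs(img - median).sum(axis=2)
        mask = dist > self.color_distance
        if not mask.any():
            return []
        b_enc = None
        out = []
        for region in regionprops(label(mask, connectivity=2)):
            if region.area < self.min_area_px:
                continue
            if b_enc is None:
                b_enc = srgb_to_b_enc(tile)
            y0, x0, y1, x1 = region.bbox
            comp_b = float(b_enc[y0:y1, x0:x1][region.image].mean())
            score = self.score_bright if comp_b > self.b_split else self.score_dark
            out.append((float(x0), float(y0), float(x1), float(y1), score))
        return out


class OnnxDetector:
    """Adapter running an ONNX object-detection model on tiles.

    Supports models emitting either already-decoded boxes ``(N, >=5)`` in
    model-space pixels or the raw single-output grid of the YOLOX family
    (``(1, n_anchors, 5 + n_classes)``), which is decoded with strides
    8/16/32 followed by greedy non-maximum suppression at the runtime's
    default IoU of 0.45.  Requires the ``onnxruntime`` extra.
    """

    def __init__(self, model_path: str | Path, nms_iou: float = 0.45):
        try:
            import onnxruntime  # noqa: PLC0415 - optional heavy dependency
        except ImportError as exc:
            raise DetectorError(
                "onnxruntime is required for the ONNX adapter; install the "
                "'onnx' extra or use the mock detector"
            ) from exc
        path = Path(model_path)
        if not path.is_file():
            raise DetectorError(f"model file {path} not found")
        try:
            self.session = onnxruntime.InferenceSession(str(path))
        except Exception as exc:  # pragma: no cover - runtime specific
            raise DetectorError(f"could not load model {path}: {exc}") from exc
        self.nms_iou = nms_iou
        self.input_name = self.session.get_inputs()[0].name

    def __call__(self, tile: np.ndarray) -> list[tuple[float, float, float, float, float]]:
        _check_rgb(tile)
        from skimage.transform import resize

        size = tiler.MODEL_INPUT
        img = resize(tile, (size, size), preserve_range=True, anti_aliasing=True)
        blob = img.astype(np.float32).transpose(2, 0, 1)[None]
        (output,) = self.session.run(None, {self.input_name: blob})
        output = np.asarray(output)
        if output.ndim == 3:
            boxes = _decode_yolox_grid(output[0], size)
        else:
            boxes = output.reshape(-1, output.shape[-1])[:, :5]
        boxes = _nms(boxes, self.nms_iou)
        scale = tiler.TILE_SIZE / size  # back to tile pixels for the shared contract
        return [
            (x0 * scale, y0 * scale, x1 * scale, y1 * scale, float(s))
            for x0, y0, x1, y1, s in boxes
        ]


def _check_rgb(tile: np.ndarray) -> None:
    if tile.ndim != 3 or tile.shape[2] != 3:
        raise DetectorError(f"detector input must be RGB (H, W, 3), got shape {tile.shape}")
    if tile.shape[0] != tiler.TILE_SIZE or tile.shape[1] != tiler.TILE_SIZE:
        raise DetectorError(
            f"detector input must be {tiler.TILE_SIZE}x{tiler.TILE_SIZE}, got "
            f"{tile.shape[1]}x{tile.shape[0]}"
        )


def _decode_yolox_grid(raw: np.ndarray, size: int) -> np.ndarray:
    """Decode the anchor-free YOLOX output into (x0, y0, x1, y1, score)."""
    grids, strides = [], []
    for stride in (8, 16, 32):
        n = size // stride
        ys, xs = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        grids.append(np.stack([xs, ys], axis=-1).reshape(-1, 2))
        strides.append(np.full((n * n, 1), stride))
    grid = np.concatenate(grids)
    stride = np.concatenate(strides)
    cx = (raw[:, 0:1] + grid[:, 0:1]) * stride
    cy = (raw[:, 1:2] + grid[:, 1:2]) * stride
    w = np.exp(raw[:, 2:3]) * stride
    h = np.exp(raw[:, 3:4]) * stride
    score = raw[:, 4:5] * raw[:, 5:].max(axis=1, keepdims=True)
    return np.concatenate([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2, score], axis=1)


def _nms(boxes: np.ndarray, iou_thresh: float) -> np.ndarray:
    if len(boxes) == 0:
        return boxes
    order = np.argsort(-boxes[:, 4])
    keep = []
    for i in order:
        bi = boxes[i]
        ok = True
        for j in keep:
            bj = boxes[j]
            ix0, iy0 = max(bi[0], bj[0]), max(bi[1], bj[1])
            ix1, iy1 = min(bi[2], bj[2]), min(bi[3], bj[3])
            inter = max(0.0, ix1 - ix0) * max(0.0, iy1 - iy0)
            ai = (bi[2] - bi[0]) * (bi[3] - bi[1])
            aj = (bj[2] - bj[0]) * (bj[3] - bj[1])
            if inter / (ai + aj - inter + 1e-12) > iou_thresh:
                ok = False
                break
        if ok:
            keep.append(i)
    return boxes[keep]


def detect_tile(
    tile: np.ndarray,
    spec: TileSpec,
    cfg: DetectorConfig = DetectorConfig(),
    detector=None,
) -> list[RawBox]:
    """Run a detector on one tile and return RawBoxes in model space.

    ``detector`` is any callable satisfying the tile contract; defaults to
    the mock when ``cfg.model_path`` is unset, the ONNX adapter otherwise.
    Scores below ``cfg.score_floor`` are dropped.
    """
    if detector is None:
        detector = OnnxDetector(cfg.model_path) if cfg.model_path else MockDetector()
    to_model = spec.model_input / spec.tile_size
    out = []
    for x0, y0, x1, y1, score in detector(tile):
        if score < cfg.score_floor:
            continue
        out.append(
            RawBox(
                tile=spec,
                x_min=max(0.0, x0 * to_model),
                y_min=max(0.0, y0 * to_model),
                x_max=min(float(spec.model_input), x1 * to_model),
                y_max=min(float(spec.model_input), y1 * to_model),
                score=score,
            )
        )
    return out


def detect_frame(
    frame: np.ndarray,
    timestamp: datetime,
    roi: CompositeRoi,
    cfg: DetectorConfig = DetectorConfig(),
    detector=None,
) -> pd.DataFrame:
    """Full per-frame detection: crop, tile, detect, remap, annotate color.

    Returns a detection table in the canonical schema with ``mean_b``
    computed on the composite crop and ``side`` left unassigned.
    """
    composite = tiler.crop_composite(frame, roi)
    if detector is None and not cfg.model_path:
        detector = MockDetector()
    rows = []
    for spec, tile in tiler.tile_composite(composite):
        for raw in detect_tile(tile, spec, cfg, detector):
            box = tiler.box_to_composite(raw)
            if box is None:
                continue
            x0, y0, x1, y1 = box
            rows.append(
                {
                    "timestamp": timestamp,
                    "x_min": x0,
                    "y_min": y0,
                    "x_max": x1,
                    "y_max": y1,
                    "score": raw.score,
                    "mean_b": np.nan,
                    "area_px": (x1 - x0) * (y1 - y0),
                    "height_px": y1 - y0,
                    "side": "none",
                }
            )
    df = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
    if len(df):
        df = annotate_mean_b(df, composite)
    return df
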