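"""End-to-end orchestration: filter -> FOT -> environmental statistics.

One reproducible run driven by a single config mapping (usually loaded from
YAML).  Outputs land in a directory as plain CSV plus a JSON run manifest
recording the config snapshot, input checksums and per-stage record counts,
so kept + rejected always reconciles with the raw detection count.  The
manifest deliberately contains no wall-clock information: re-running an
identical config on identical inputs is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version as pkg_version
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import envstats, fot_estimator, io_formats
from .filterchain import FilterThresholds, apply_filters
from .fot_estimator import SideSplit

__all__ = ["ConfigError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Run configuration does not satisfy the schema."""


_SCHEMA: dict[str, dict[str, type]] = {
    "inputs": {"detections": str, "weather": str, "observed_fot": str},
    "filter": {"score_min": float, "b_min": float, "area_max": int},
    "fot": {
        "left_max_x": float,
        "right_min_x": float,
        "window": list,
        "min_detections": int,
        "secondary_fraction": float,
    },
    "envstats": {"factors": list, "scan": bool, "drop_c": float, "hot_c": float},
}

_FACTOR_CHANNELS = {"temp": "temp_c", "rad": "radiation", "hum": "rh_pct", "hd": "hd"}


def validate_config(config: Mapping[str, Any]) -> dict:
    """Check the run config against the schema; returns a normalized copy."""
    bad: list[str] = []
    cfg = {k: dict(v) if isinstance(v, Mapping) else v for k, v in config.items()}
    for section, val in cfg.items():
        if section in ("seed", "output_dir"):
            continue
        if section not in _SCHEMA:
            bad.append(section)
            continue
        for key in val:
            if key not in _SCHEMA[section]:
                bad.append(f"{section}.{key}")
    inputs = cfg.get("inputs", {})
    if "detections" not in inputs:
        bad.append("inputs.detections (required)")
    needs_weather = bool(cfg.get("envstats"))
    if needs_weather and "weather" not in inputs:
        bad.append("inputs.weather (required when envstats is configured)")
    if bad:
        raise ConfigError(f"invalid config keys: {bad}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: Mapping[str, Any], output_dir: str | Path | None = None) -> dict:
    """Execute the configured stages and write outputs plus manifest.json.

    Writes ``fot.csv`` always; ``table1.csv`` (daytime-mean factor
    correlations), ``scan.csv`` (trailing-window sensitivity scan) and
    ``drops.csv`` (temperature-drop fractions) when envstats is configured;
    ``validation.json`` when an observed-FOT table is supplied.  Returns the
    manifest dict.
    """
    cfg = validate_config(config)
    out_dir = Path(output_dir or cfg.get("output_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)

    inputs = cfg["inputs"]
    det_path = Path(inputs["detections"])
    detections = io_formats.load_detections(det_path)
    checksums = {"detections": _sha256(det_path)}

    fcfg = cfg.get("filter", {})
    thresholds = FilterThresholds(
        score_min=float(fcfg.get("score_min", 0.7)),
        b_min=float(fcfg.get("b_min", 140.0)),
        area_max=int(fcfg.get("area_max", 6000)),
    )
    kept, rejected = apply_filters(detections, thresholds)
    reject_counts = (
        rejected["reject_reasons"].value_counts().sort_index().to_dict() if len(rejected) else {}
    )

    pcfg = cfg.get("fot", {})
    split = SideSplit(
        float(pcfg.get("left_max_x", 1350.0)), float(pcfg.get("right_min_x", 1450.0))
    )
    window = tuple(pcfg.get("window", (6.0, 18.0)))
    frame_ts = pd.to_datetime(detections["timestamp"]).drop_duplicates()
    index_series = fot_estimator.flower_index_series(kept, frame_ts, split)
    estimates = fot_estimator.estimate_fot_table(
        index_series,
        window=window,  # type: ignore[arg-type]
        min_detections=int(pcfg.get("min_detections", 3)),
        secondary_fraction=float(pcfg.get("secondary_fraction", 0.25)),
    )
    estimates.to_csv(out_dir / "fot.csv", index=False)

    ecfg = cfg.get("envstats")
    weather = None
    if ecfg or "observed_fot" in inputs:
        if "weather" in inputs:
            wpath = Path(inputs["weather"])
            weather = io_formats.load_weather_csv(wpath)
            checksums["weather"] = _sha256(wpath)

    if ecfg and weather is not None:
        weather = envstats.add_humidity_deficit(weather)
        factors = ecfg.get("factors", ["temp", "rad", "hum", "hd"])
        rows = []
        for side in ("left", "right"):
            sub = estimates[(estimates["side"] == side) & (~estimates["excluded"])]
            fot_by_date = dict(zip(sub["date"], sub["fot_est"]))
            if len(fot_by_date) >= 3:
                means = envstats.daytime_mean_table(
                    weather, sorted(fot_by_date), channels=[_FACTOR_CHANNELS[f] for f in factors]
                )
                fots = [fot_by_date[d] for d in means["date"]]
                for f in factors:
                    try:
                        res = envstats.pearson_correlation(
                            means[_FACTOR_CHANNELS[f]], fots, factor=f
                        )
                        rows.append(
                            {"side": side, "factor": f, "r": res.r, "p": res.p, "n": res.n}
                        )
                    except envstats.UndefinedCorrelation:
                        rows.append(
                            {"side": side, "factor": f, "r": np.nan, "p": np.nan, "n": len(fots)}
                        )
        pd.DataFrame(rows, columns=["side", "factor", "r", "p", "n"]).to_csv(
            out_dir / "table1.csv", index=False
        )

        if ecfg.get("scan", True):
            scans = []
            for side in ("left", "right"):
                sub = estimates[(estimates["side"] == side) & (~estimates["excluded"])]
                scan = envstats.sensitivity_scan(
                    dict(zip(sub["date"], sub["fot_est"])), weather
                )
                scan.insert(0, "side", side)
                scans.append(scan)
            pd.concat(scans, ignore_index=True).to_csv(out_dir / "scan.csv", index=False)

        drop_rows = []
        for side in ("left", "right"):
            sub = estimates[(estimates["side"] == side) & (~estimates["excluded"])]
            da = envstats.drop_analysis(
                weather,
                dict(zip(sub["date"], sub["fot_est"])),
                drop_c=float(ecfg.get("drop_c", 0.5)),
                hot_c=float(ecfg.get("hot_c", 35.0)),
            )
            frame = da.as_frame()
            frame.insert(0, "side", side)
            drop_rows.append(frame)
        pd.concat(drop_rows, ignore_index=True).to_csv(out_dir / "drops.csv", index=False)

    validation = None
    if "observed_fot" in inputs:
        opath = Path(inputs["observed_fot"])
        observed = io_formats.load_observed_fot(opath)
        checksums["observed_fot"] = _sha256(opath)
        val = fot_estimator.fot_rmse(estimates, observed)
        validation = {"rmse_h": val.rmse_h, "mean_error_h": val.mean_error_h, "n": val.n}
        (out_dir / "validation.json").write_text(json.dumps(validation, indent=2, sort_keys=True))

    try:
        ver = pkg_version("fotscope")
    except PackageNotFoundError:  # pragma: no cover
        ver = "unknown"
    manifest = {
        "config": cfg,
        "input_checksums": checksums,
        "counts": {
            "frames": int(frame_ts.nunique()),
            "raw_detections": int(len(detections)),
            "kept": int(len(kept)),
            "rejected": int(len(rejected)),
            "rejected_by_reason": reject_counts,
            "days": int(estimates["date"].nunique()),
            "excluded_day_sides": int(estimates["excluded"].sum()),
        },
        "seed": cfg.get("seed"),
        "version": ver,
        "validation": validation,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
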