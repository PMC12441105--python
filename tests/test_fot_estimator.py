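"""Flower index, spline smoothing, daily peak extraction and validation."""

import math
from datetime import date, datetime, time, timedelta

import numpy as np
import pandas as pd
import pytest

from fotscope import synthfield as sf
from fotscope.fot_estimator import (
    ALTERNATE_SPLIT,
    InsufficientSupport,
    SideSplit,
    assign_side,
    estimate_fot,
    estimate_fot_table,
    flower_index_series,
    fot_rmse,
    neighboring_day_diff,
    smooth_series,
)

DAY = date(2022, 8, 16)


def day_series(hours, values, side="left", n_boxes=None):
    ts = [datetime.combine(DAY, time(0, 0)) + timedelta(hours=h) for h in hours]
    if n_boxes is None:
        n_boxes = [int(v > 0) for v in values]
    return pd.DataFrame({"timestamp": ts, "side": side, "index": values, "n_boxes": n_boxes})


class TestAssignSide:
    @pytest.mark.parametrize(
        "center,split,expected",
        [
            (1000.0, SideSplit(), "left"),
            (1400.0, SideSplit(), "none"),  # dead zone 1350-1450
            (2000.0, SideSplit(), "right"),
            (700.0, ALTERNATE_SPLIT, "none"),  # dead zone 650-750
            (600.0, ALTERNATE_SPLIT, "left"),
        ],
    )
    def test_center_rule(self, center, split, expected):
        assert assign_side(center, split) == expected


class TestFlowerIndex:
    def grid(self, n=6):
        return pd.date_range(datetime.combine(DAY, time(11, 0)), periods=n, freq="10min")

    def make_kept(self, rows):
        return pd.DataFrame(
            rows, columns=["timestamp", "x_min", "y_min", "x_max", "y_max", "height_px", "side"]
        ).assign(score=0.9, mean_b=200.0, area_px=1000)

    def test_index_is_sum_of_heights(self):
        ts = self.grid()[0]
        kept = self.make_kept(
            [
                (ts, 100, 0, 150, 30, 30, "left"),
                (ts, 300, 0, 360, 50, 50, "left"),
                (ts, 500, 0, 560, 20, 20, "left"),
            ]
        )
        series = flower_index_series(kept, self.grid())
        left = series[(series.side == "left") & (series.timestamp == ts)]
        assert left["index"].iloc[0] == 100
        assert left["n_boxes"].iloc[0] == 3

    def test_no_boxes_gives_zero_on_full_grid(self):
        series = flower_index_series(self.make_kept([]), self.grid())
        assert len(series) == 2 * 6
        assert (series["index"] == 0).all()

    def test_no_side_leakage(self):
        ts = self.grid()[0]
        kept = self.make_kept(
            [(ts, 100, 0, 160, 30, 30, "left"), (ts, 2000, 0, 2060, 50, 50, "right")]
        )
        series = flower_index_series(kept, self.grid())
        at = series[series.timestamp == ts].set_index("side")["index"]
        assert at["left"] == 30 and at["right"] == 50

    def test_additive_over_partition(self, detection_stream):
        det, _ = detection_stream
        kept = det[det.is_true]
        grid = kept["timestamp"].drop_duplicates()
        full = flower_index_series(kept, grid)
        half_a = flower_index_series(kept.iloc[::2], grid)
        half_b = flower_index_series(kept.iloc[1::2], grid)
        merged = half_a.merge(half_b, on=["timestamp", "side"], suffixes=("_a", "_b"))
        merged = merged.merge(full, on=["timestamp", "side"])
        assert (merged["index_a"] + merged["index_b"] == merged["index"]).all()


class TestSmoothing:
    def test_gaussian_profile_peak_recovered(self):
        hours = np.arange(6.0, 18.01, 1 / 6)  # 10-min grid
        truth = 11 + 40 / 60
        values = 100 * np.exp(-0.5 * ((hours - truth) / 0.35) ** 2)
        curve, _ = smooth_series(hours, values)
        grid = np.arange(6 * 60, 18 * 60 + 1) / 60.0
        peak = grid[np.argmax(curve(grid))]
        assert abs(peak - truth) <= 10 / 60

    def test_constant_series_gives_constant_curve(self):
        hours = np.arange(6.0, 18.01, 1 / 6)
        curve, lam = smooth_series(hours, np.full_like(hours, 5.0))
        assert np.allclose(curve(np.array([7.0, 12.0, 17.0])), 5.0)

    def test_three_points_insufficient(self):
        with pytest.raises(InsufficientSupport):
            smooth_series(np.array([10.0, 10.5, 11.0]), np.array([1.0, 2.0, 1.0]))

    def test_constant_shift_moves_curve_not_argmax(self):
        hours = np.arange(6.0, 18.01, 1 / 6)
        values = 100 * np.exp(-0.5 * ((hours - 11.5) / 0.4) ** 2)
        grid = np.arange(6 * 60, 18 * 60 + 1) / 60.0
        c0, _ = smooth_series(hours, values)
        c1, _ = smooth_series(hours, values + 50.0)
        v0, v1 = np.asarray(c0(grid)), np.asarray(c1(grid))
        assert np.argmax(v0) == np.argmax(v1)
        assert np.allclose(v1 - v0, 50.0, atol=1e-6)


class TestEstimateFot:
    def gaussian_day(self, truth=11 + 40 / 60, n_boxes=30, amp=100.0):
        hours = np.arange(6.0, 18.01, 1 / 6)
        values = amp * np.exp(-0.5 * ((hours - truth) / 0.35) ** 2)
        nb = np.zeros(len(hours), dtype=int)
        nb[np.argmax(values)] = n_boxes
        return day_series(hours, values, n_boxes=nb)

    def test_recovers_true_peak_time(self):
        est = estimate_fot(self.gaussian_day())
        assert not est.excluded
        assert abs(est.fot_est - (11 + 40 / 60)) <= 10 / 60

    def test_two_detections_excluded(self):
        est = estimate_fot(self.gaussian_day(n_boxes=2))
        assert est.excluded and est.fot_est is None

    def test_exclusion_flips_when_boxes_removed(self):
        series = self.gaussian_day(n_boxes=5)
        for n in (5, 4, 3, 2, 1, 0):
            est = estimate_fot(series, n_detections=n)
            assert est.excluded == (n < 3)

    def test_bimodal_day_reports_secondary_peak(self):
        hours = np.arange(6.0, 18.01, 1 / 6)
        values = 100 * np.exp(-0.5 * ((hours - 11.5) / 0.3) ** 2) + 60 * np.exp(
            -0.5 * ((hours - (13 + 40 / 60)) / 0.3) ** 2
        )
        est = estimate_fot(day_series(hours, values, n_boxes=[5] * len(hours)))
        assert abs(est.fot_est - 11.5) <= 10 / 60
        assert est.secondary_peaks, "expected a reported secondary peak"
        times = [t for t, _ in est.secondary_peaks]
        assert any(abs(t - (13 + 40 / 60)) <= 15 / 60 for t in times)

    def test_parameter_recovery_on_synthetic_days(self, detection_stream, fot_profile):
        det, truth = detection_stream
        kept = det[det.is_true]
        grid = sf.frame_grid(
            sf.SceneConfig(fot_profile=truth.fot_true), sorted({d for d, _ in truth.fot_true})
        )
        series = flower_index_series(kept, grid)
        est = estimate_fot_table(series)
        ok = est[~est.excluded].copy()
        errors = np.array(
            [abs(row.fot_est - truth.fot_true[(row.date, row.side)]) for row in ok.itertuples()]
        )
        assert len(ok) >= 35  # 20 days x 2 sides, a few sparse day-sides may drop
        assert np.median(errors) * 60 <= 10.0
        assert math.sqrt(np.mean(errors**2)) <= 0.25


class TestValidationStats:
    def make_estimates(self, pairs):
        return pd.DataFrame(
            [
                {"date": d, "side": s, "fot_est": v, "excluded": False}
                for (d, s), v in pairs.items()
            ]
        )

    def test_identical_series_zero_rmse(self):
        pairs = {(DAY, "left"): 11.5, (DAY + timedelta(days=1), "left"): 12.0}
        est = self.make_estimates(pairs)
        obs = pd.DataFrame(
            [{"date": d, "side": s, "fot_observed": v} for (d, s), v in pairs.items()]
        )
        val = fot_rmse(est, obs)
        assert val.rmse_h == 0.0 and val.n == 2

    def test_half_hour_offset(self):
        est = self.make_estimates({(DAY, "left"): 12.0})
        obs = pd.DataFrame([{"date": DAY, "side": "left", "fot_observed": 11.5}])
        val = fot_rmse(est, obs)
        assert val.rmse_h == pytest.approx(0.5)
        assert val.mean_error_h == pytest.approx(0.5)

    def test_symmetric_errors_cancel_in_mean(self):
        est = self.make_estimates({(DAY, "left"): 11.8, (DAY + timedelta(days=1), "left"): 11.2})
        obs = pd.DataFrame(
            [
                {"date": DAY, "side": "left", "fot_observed": 11.5},
                {"date": DAY + timedelta(days=1), "side": "left", "fot_observed": 11.5},
            ]
        )
        val = fot_rmse(est, obs)
        assert val.rmse_h == pytest.approx(0.3)
        assert val.mean_error_h == pytest.approx(0.0, abs=1e-12)

    def test_empty_join_is_an_error(self):
        est = self.make_estimates({(DAY, "left"): 12.0})
        obs = pd.DataFrame([{"date": DAY, "side": "right", "fot_observed": 11.5}])
        with pytest.raises(ValueError, match="no overlapping"):
            fot_rmse(est, obs)

    def test_neighboring_day_diffs(self):
        days = [DAY + timedelta(days=i) for i in range(3)]
        est = self.make_estimates(
            {(days[0], "left"): 12.0, (days[1], "left"): 12.5, (days[2], "left"): 12.0}
        )
        mean, sd, n = neighboring_day_diff(est)
        assert mean == pytest.approx(30.0)
        assert sd == pytest.approx(0.0)
        assert n == 2

    def test_date_gap_breaks_adjacency(self):
        est = self.make_estimates({(DAY, "left"): 12.0, (DAY + timedelta(days=2), "left"): 12.5})
        with pytest.raises(ValueError, match="consecutive"):
            neighboring_day_diff(est)
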