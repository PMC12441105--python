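"""Environmental layer: humidity deficit, correlations, scan, drops, rank tests."""

import math
from datetime import date, datetime, time, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fotscope import envstats as es
from fotscope import synthfield as sf


def hd_oracle(T, H):
    """Independent evaluation of the printed humidity-deficit equation."""
    return 217.0 / (T + 273.15) * (6.11 * 10 ** (7.5 * T / (T + 237.3))) * ((100 - H) / 100.0)


class TestHumidityDeficit:
    @pytest.mark.parametrize("T", [0, 10, 20, 25, 30, 40])
    def test_zero_at_saturation(self, T):
        assert es.humidity_deficit(T, 100.0) == 0.0

    def test_reference_value_25C_50pct(self):
        assert es.humidity_deficit(25.0, 50.0) == pytest.approx(hd_oracle(25.0, 50.0), rel=1e-12)
        assert es.humidity_deficit(25.0, 50.0) == pytest.approx(11.5, abs=0.1)

    @settings(deadline=None, max_examples=100)
    @given(T=st.floats(-10, 45), H=st.floats(0, 100))
    def test_matches_oracle_and_nonnegative(self, T, H):
        v = es.humidity_deficit(T, H)
        assert v >= 0.0
        assert v == pytest.approx(hd_oracle(T, H), rel=1e-9, abs=1e-12)

    def test_monotone_increasing_in_T(self):
        grid = np.arange(0.0, 41.0, 10.0)
        vals = es.humidity_deficit(grid, 50.0)
        assert np.all(np.diff(vals) > 0)

    def test_monotone_decreasing_in_H(self):
        vals = es.humidity_deficit(30.0, np.arange(0.0, 101.0, 10.0))
        assert np.all(np.diff(vals) < 0)

    def test_bad_humidity_rejected(self):
        with pytest.raises(ValueError):
            es.humidity_deficit(25.0, 101.0)


def flat_weather(day, temp=28.0, cadence=10):
    ts = pd.date_range(datetime.combine(day, time(0, 0)), periods=24 * 60 // cadence, freq=f"{cadence}min")
    return pd.DataFrame({"timestamp": ts, "temp_c": temp, "rh_pct": 60.0, "radiation": 100.0})


class TestDaytimeMean:
    DAY = date(2022, 8, 16)

    def test_constant_day(self):
        v, n = es.daytime_mean(flat_weather(self.DAY), self.DAY)
        assert v == 28.0
        assert n == 43  # 8:00..15:00 inclusive on a 10-min grid

    def test_linear_ramp_gives_midpoint(self):
        w = flat_weather(self.DAY)
        h = pd.to_datetime(w.timestamp).dt.hour + pd.to_datetime(w.timestamp).dt.minute / 60
        w["temp_c"] = 20.0 + 1.0 * h
        v, _ = es.daytime_mean(w, self.DAY)
        assert v == pytest.approx(20.0 + (8.0 + 15.0) / 2)

    def test_absent_date_is_missing(self):
        v, n = es.daytime_mean(flat_weather(self.DAY), self.DAY + timedelta(days=1))
        assert math.isnan(v) and n == 0


def pearson_oracle(x, y):
    """Textbook direct-formula Pearson r and two-sided t-based p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xm, ym = x - x.mean(), y - y.mean()
    r = (xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum())
    from scipy.stats import t as tdist

    t = r * math.sqrt((n - 2) / (1 - r**2))
    p = 2 * tdist.sf(abs(t), n - 2)
    return r, p


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = es.pearson_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_matches_direct_formula_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=30)
            y = 0.3 * x + rng.normal(size=30)
            res = es.pearson_correlation(x, y)
            r0, p0 = pearson_oracle(x, y)
            assert res.r == pytest.approx(r0, abs=1e-12)
            assert res.p == pytest.approx(p0, rel=1e-9)

    def test_null_simulation_small_r(self, rng):
        x = rng.normal(size=2000)
        y = rng.normal(size=2000)
        res = es.pearson_correlation(x, y)
        assert abs(res.r) < 0.1

    def test_zero_variance_undefined(self):
        with pytest.raises(es.UndefinedCorrelation):
            es.pearson_correlation(np.ones(10), np.arange(10.0))


class TestTrailingWindow:
    DAY = date(2022, 8, 16)

    def test_right_closed_left_open_membership(self):
        w = flat_weather(self.DAY)
        h = pd.to_datetime(w.timestamp)
        w["temp_c"] = np.arange(len(w), dtype=float)  # value = record ordinal
        at = datetime.combine(self.DAY, time(10, 10))
        v = es.trailing_window_mean_T(w, at)
        # records (9:10, 10:10] are ordinals 56..61
        assert v == pytest.approx(np.mean([56, 57, 58, 59, 60, 61]))

    def test_off_grid_clock_time(self):
        w = flat_weather(self.DAY)
        w["temp_c"] = np.arange(len(w), dtype=float)
        v = es.trailing_window_mean_T(w, datetime.combine(self.DAY, time(10, 15)))
        # (9:15, 10:15] still holds records 9:20..10:10 -> ordinals 56..61
        assert v == pytest.approx(np.mean([56, 57, 58, 59, 60, 61]))

    def test_empty_window_missing(self):
        w = flat_weather(self.DAY)
        v = es.trailing_window_mean_T(w, datetime.combine(self.DAY - timedelta(days=1), time(3, 0)))
        assert math.isnan(v)


class TestSensitivityScan:
    def test_recovers_engineered_window_exactly(self, weather_series, campaign_dates):
        weather, _ = weather_series
        target = time(10, 10)
        fot = {
            d: 12.0 - 0.05 * es.trailing_window_mean_T(weather, datetime.combine(d, target))
            for d in campaign_dates
        }
        scan = es.sensitivity_scan(fot, weather, start_hour=6.0, end_hour=16.0)
        t, r = es.scan_argmin(scan)
        assert t == pytest.approx(10 + 10 / 60, abs=1e-9)
        assert r == pytest.approx(-1.0, abs=1e-9)

    def test_null_profile_has_no_strong_negative(self, weather_series, campaign_dates, rng):
        weather, _ = weather_series
        fot = {d: float(rng.uniform(10, 14)) for d in campaign_dates}
        scan = es.sensitivity_scan(fot, weather, start_hour=6.0, end_hour=16.0)
        _, r = es.scan_argmin(scan)
        assert r > -0.9  # independent FOT never correlates perfectly

    def test_single_date_all_missing(self, weather_series):
        weather, _ = weather_series
        day = pd.to_datetime(weather.timestamp).dt.date.iloc[0]
        scan = es.sensitivity_scan({day: 11.0}, weather, start_hour=8.0, end_hour=12.0)
        assert scan["r"].isna().all()


class TestTempAtFot:
    DAY = date(2022, 8, 16)

    def test_nearest_record(self):
        w = flat_weather(self.DAY)
        w["temp_c"] = np.arange(len(w), dtype=float)
        # 11:41 -> nearest record 11:40 (ordinal 70)
        assert es.temp_at_fot(w, self.DAY, 11 + 41 / 60) == 70.0

    def test_tie_goes_earlier(self):
        w = flat_weather(self.DAY)
        w["temp_c"] = np.arange(len(w), dtype=float)
        # 11:45 is equidistant between 11:40 (70) and 11:50 (71)
        assert es.temp_at_fot(w, self.DAY, 11.75) == 70.0

    def test_outside_span_missing(self):
        w = flat_weather(self.DAY)
        w = w[pd.to_datetime(w.timestamp).dt.hour >= 6]
        assert math.isnan(es.temp_at_fot(w, self.DAY, 3.0))


class TestDropAnalysis:
    def test_difference_arithmetic(self):
        day = date(2022, 8, 16)
        ts = pd.date_range(datetime.combine(day, time(11, 0)), periods=3, freq="10min")
        w = pd.DataFrame(
            {"timestamp": ts, "temp_c": [30.0, 30.2, 29.6], "rh_pct": 60.0, "radiation": 0.0}
        )
        da = es.drop_analysis(w, {day: 11 + 20 / 60}, grid_min=[0])
        # Delta T at 11:20 = -0.6 < -0.5: counted at rho = 0
        assert da.frac_cool[0] == 1.0

    def test_constant_days_all_zero(self, campaign_dates):
        w = pd.concat([flat_weather(d) for d in campaign_dates[:5]], ignore_index=True)
        da = es.drop_analysis(w, {d: 11.5 for d in campaign_dates[:5]})
        assert np.nansum(da.frac_cool) == 0.0

    def test_injected_dip_fractions_match_event_log(self, campaign_dates):
        # 10 hot days (6 dipped), 10 cool days (1 dipped), dip at FOT-10 min
        means = {d: (33.0 if i < 10 else 28.0) for i, d in enumerate(campaign_dates)}
        fot = {d: 11.5 for d in campaign_dates}
        dipped = campaign_dates[:6] + [campaign_dates[10]]
        dips = tuple((datetime.combine(d, time(11, 20)), 0.7) for d in dipped)
        cfg = sf.WeatherConfig(daily_mean_t=means, dips=dips)
        weather, truth = sf.generate_weather(cfg, seed=12)
        assert len(truth.hot_days) == 10
        da = es.drop_analysis(weather, fot)
        at = list(da.grid_min).index(-10)
        assert da.frac_hot[at] == pytest.approx(0.6)
        assert da.frac_cool[at] == pytest.approx(0.1)
        # brute-force recount from the generator's event log
        assert da.n_hot == 10 and da.n_cool == 10
        expect_hot = sum(1 for d, _ in truth.dips if d.date() in truth.hot_days) / da.n_hot
        assert da.frac_hot[at] == pytest.approx(expect_hot)


class TestGroupCompare:
    def test_identical_samples_p_one(self):
        g = {"a": list(range(10)), "b": list(range(10))}
        mat = es.group_compare(g)
        assert mat.loc["a", "b"] == pytest.approx(1.0)

    def test_fully_separated_samples_minimal_p(self):
        from scipy.stats import mannwhitneyu

        a = list(range(1, 11))
        b = list(range(101, 111))
        mat = es.group_compare({"a": a, "b": b})
        expected = mannwhitneyu(a, b, alternative="two-sided").pvalue
        assert mat.loc["a", "b"] == pytest.approx(expected)
        assert mat.loc["a", "b"] < 0.001

    def test_three_groups_symmetric_unit_diagonal(self, rng):
        g = {k: rng.normal(size=12).tolist() for k in "abc"}
        mat = es.group_compare(g)
        assert (np.diag(mat.values) == 1.0).all()
        assert np.allclose(mat.values, mat.values.T)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            es.group_compare({"a": [1.0], "b": [1.0, 2.0]})

    def test_type_one_error_near_nominal(self, rng):
        # permuted identical-distribution groups: rejection rate at alpha=0.05
        # within binomial 99% bounds over 1000 replicates
        alpha = 0.05
        n_rep = 1000
        rejects = 0
        from scipy.stats import mannwhitneyu

        for _ in range(n_rep):
            a = rng.normal(size=30)
            b = rng.normal(size=30)
            if mannwhitneyu(a, b, alternative="two-sided").pvalue <= alpha:
                rejects += 1
        rate = rejects / n_rep
        half = 2.576 * math.sqrt(alpha * (1 - alpha) / n_rep)
        assert alpha - half <= rate <= alpha + half
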