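"""Shared fixtures: small synthetic campaigns with known ground truth."""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pytest

from fotscope import synthfield as sf


@pytest.fixture
def rng():
    return np.random.default_rng(20220816)


@pytest.fixture
def campaign_dates():
    return [date(2022, 8, 1) + timedelta(days=i) for i in range(20)]


@pytest.fixture
def fot_profile(rng, campaign_dates):
    """True FOTs drawn over the morning-to-afternoon anthesis range."""
    return {
        (d, s): float(rng.uniform(9.0, 14.5))
        for d in campaign_dates
        for s in ("left", "right")
    }


@pytest.fixture
def scene_config(fot_profile):
    return sf.SceneConfig(
        fot_profile=fot_profile,
        flowers_per_day_mean=15.0,
        shadow_rate_per_day=5.0,
        lowscore_rate_per_day=5.0,
    )


@pytest.fixture
def detection_stream(scene_config):
    return sf.generate_detections(scene_config, seed=42)


@pytest.fixture
def weather_series(rng, campaign_dates):
    means = {d: float(rng.uniform(26.0, 34.0)) for d in campaign_dates}
    return sf.generate_weather(sf.WeatherConfig(daily_mean_t=means), seed=11)
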