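"""Transient temperature drops before flower opening on hot days.

Classifies days by whether the daily maximum exceeds 35 degC, then asks on
what fraction of each class a >0.5 degC drop within 10 min occurred at each
offset relative to the FOT.  Dips are injected on 6 of 10 hot days and 1 of
10 non-hot days at FOT-10 min, and the analysis reads them back exactly.
"""

from datetime import date, datetime, time, timedelta

from fotscope import synthfield as sf
from fotscope.envstats import drop_analysis

dates = [date(2022, 8, 1) + timedelta(days=i) for i in range(20)]
means = {d: (33.0 if i < 10 else 28.0) for i, d in enumerate(dates)}
fot = {d: 11.5 for d in dates}
dipped = dates[:6] + [dates[10]]
dips = tuple((datetime.combine(d, time(11, 20)), 0.7) for d in dipped)

weather, truth = sf.generate_weather(sf.WeatherConfig(daily_mean_t=means, dips=dips), seed=12)
print(f"hot days (max T > 35 degC): {len(truth.hot_days)} of {len(dates)}")

da = drop_analysis(weather, fot)
print("\nrel. time (min)  frac hot  frac non-hot")
for rel, fh, fc in zip(da.grid_min, da.frac_hot, da.frac_cool):
    if abs(rel) <= 30:
        print(f"{rel:14d}  {fh:8.2f}  {fc:12.2f}")
# The 0.60 vs 0.10 spike at -10 min is exactly the injected dip pattern:
# a sharp pre-opening cooling event distinguishes hot days.
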