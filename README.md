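# fotscope

Automated estimation of the daily **flower-opening time (FOT)** of rice from
fixed-camera time-lapse imagery, with an environmental analysis layer linking
FOT to weather.

Rice spikelets open once, for under an hour, and *when* in the day they open
matters: earlier opening escapes afternoon heat stress, and FOT differences
between the *indica* and *japonica* subspecies are an obstacle to hybrid
breeding. `fotscope` turns the output of an object detector run on tiled
greenhouse images into a daily FOT estimate per cultivar, and quantifies how
that time responds to temperature, humidity, radiation and transient
temperature drops.

## What it computes

A camera records frames every 10 min; a detector (any model emitting boxes
with confidence scores — a deterministic mock is built in) is run on the
2800×2800 analysis region after splitting it into 16 tiles of 700×700
(resized to the 640×640 model input). `fotscope` then:

1. **Filters false positives.** A detected region is kept iff
   `score > 0.7` **and** mean CIE L\*a\*b\* *b* > 140 (8-bit offset encoding;
   yellow panicles sit near 150, shadow artifacts well below 140) **and**
   area < 6000 px.
2. **Builds the flower index.** Per frame and scene side (left/right half,
   one cultivar each, with a dead zone between), the index is
   Σ height of kept boxes — a proxy for the number of simultaneously open
   flowers.
3. **Estimates the FOT.** Per day and side, the diel index series is fitted
   with a cubic smoothing spline (penalty chosen by generalized
   cross-validation) and the FOT is the time of the highest peak on a
   1-minute grid. Days with < 3 kept detections are excluded. Secondary
   peaks (split flowering events) are reported.
4. **Relates FOT to weather.** Humidity deficit
   `HD = 217/(T+273.15) · 6.11·10^(7.5T/(T+237.3)) · (100−H)/100` (g·m⁻³);
   Pearson correlations of FOT with 8:00–15:00 daytime means; a sensitivity
   scan correlating FOT with the trailing 1-h mean temperature at every
   clock time; temperature at FOT; the fraction of hot days (max > 35 °C)
   showing a > 0.5 °C / 10 min temperature drop at each offset around the
   FOT; pairwise Wilcoxon group comparisons with Holm adjustment.

A synthetic study generator (`fotscope.synthfield`) produces detection
streams, rendered scenes and diel weather with complete ground truth, so the
whole chain is testable against known answers.

## Worked example

```bash
python examples/01_fot_from_detections.py
```

builds a 10-day synthetic campaign, filters it and estimates every day-side:

```
filter kept 297/392 boxes (95 false positives removed)

date        side   estimated  true   error(min)
2022-08-01  left   12:15      12:19     3.8
2022-08-01  right  13:34      13:32     1.8
...
median |error| = 6.8 min over 20 day-sides
```

The median error is under one 10-min frame interval: the spline peak lands
on the frame at which the generator actually opened its flowers. The other
examples demonstrate the humidity deficit (`02`), exact recovery of an
engineered temperature-sensitive window at 10:10 with r = −1 (`03`), the
hot-day drop-trigger fractions (`04`), and tiled mock detection on a
rendered scene (`05`).

The same flows are scriptable from a shell:

```bash
fotscope simulate --seed 7 --out-dir sim --n-days 10
fotscope run --config run.yaml          # filter -> FOT -> envstats + manifest
fotscope fot --in det_filtered.csv --split 1350:1450 --out fot.csv
```

## Layout

- `src/fotscope/` — `tiler` (crop/tile/box remap), `detector` (contract,
  mock, ONNX adapter), `filterchain` (Lab color + filter), `fot_estimator`
  (index, spline, peaks, validation), `envstats` (HD, correlations, scan,
  drops, rank tests), `synthfield` (generator), `io_formats`, `pipeline`,
  `cli`.
- `examples/` — one short narrative script per capability.
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
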