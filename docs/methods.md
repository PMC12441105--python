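# Methods

## Problem setting

A fixed camera photographs four potted rice plants (two per cultivar, one
cultivar per half of the scene) every 10 minutes. An object detector marks
regions of open flowers on each frame. The quantity of interest is the
daily flower-opening time (FOT): the clock time at which the number of
simultaneously open flowers peaks, per day and per cultivar side. The
package estimates FOT from the detection stream and analyses its
relationship to weather recorded by a co-located logger at the same
10-minute cadence.

## Geometry

The analysis region is a fixed 2800×2800 crop of the raw frame (default:
centered; the offset is configurable because camera placement varies by
session). It is partitioned into a 4×4 grid of 700×700 tiles; each tile is
resized to the detector's 640×640 input. Detector boxes are mapped back by
the exact rational factor 700/640, rounded half-away-from-zero to integer
pixels, and offset by the tile origin. Coordinates are 0-based, half-open,
so box area is exactly width×height. Boxes are deliberately **not** merged
across tile boundaries: a flower straddling a boundary may contribute two
boxes, which is harmless because the flower index sums heights rather than
counting regions. Tiling and reassembly are exact inverses (tested
bit-exactly).

## False-positive filter

Detected regions are kept iff all three strict inequalities hold:
confidence score > 0.7, mean *b* > 140, area < 6000 px. The *b* feature is
the blue–yellow axis of CIE L\*a\*b\* (D65, sRGB input) in the common 8-bit
offset encoding `b_enc = clamp(b* + 128, 0, 255)`: the neutral axis maps to
128, mature yellow panicles near 150–200, dark bluish shadow artifacts
below 140. The thresholds are only meaningful on this 0–255 scale, which is
why the offset encoding is fixed rather than configurable. `mean_b` is
computed on the full-resolution composite crop (not the resized model
input) so that color and the pixel-area threshold refer to the same
resolution. Boundary semantics are strict as stated; rejected records are
labeled with every failed criterion so filter provenance is auditable.

## Flower index and side split

At each frame time the flower index per side is the sum of kept-box pixel
heights. Region height correlates with the number of open flowers in the
region better than the raw region count, because synchronously opening
spikelets merge into tall regions. A box belongs to the side containing its
**center** x; centers inside the dead zone (default 1350–1450 px; an
alternate 650/750 profile covers sessions with a different pot layout)
belong to neither side. The center rule is a choice — a region spanning the
dead zone has no unambiguous side — and is symmetric and deterministic.
Frames with no kept boxes contribute index 0, so each day has a complete
diel series.

## FOT estimation

Per calendar day and side, the index series is fitted with a cubic
smoothing spline minimising RSS + λ∫(f″)², with λ selected by generalized
cross-validation (`scipy.interpolate.make_smoothing_spline`), matching the
default behaviour of the standard statistical smoothing-spline routine.
Zero-index frames are included in the fit (the peak is defined against the
whole diel series). The FOT is the argmax of the smoothed curve on a
1-minute grid restricted to a search window (default 6:00–18:00,
intersected with the day's observation span) to avoid nocturnal spline
artifacts; ties break to the earliest time. Days with fewer than 3 kept
detections carry no meaningful peak and are flagged excluded instead of
estimated. Interior local maxima at or above 25% of the global peak are
reported as secondary peaks; split flowering events (distinct morning and
afternoon openings of panicles at different developmental stages) show up
there. The 25% fraction is a reporting knob, not part of the estimate.
Fitting is per day; a whole-series fit sliced by day was considered and
rejected as the default because day boundaries are natural discontinuities
in flowering.

Degenerate inputs: a constant day's series short-circuits to a constant
curve (GCV is undefined there) and the tie rule yields the window start;
days with fewer than 4 distinct frame times fall back to the raw argmax.
The GCV-selected λ is not exposed by the spline routine and is recorded
only when the caller fixes λ explicitly.

Validation against manually observed FOTs uses RMSE in decimal hours on the
(date, side) join, plus the mean signed error; day-to-day variability is
summarised as the mean ± SD (n−1) of |ΔFOT| between consecutive calendar
dates that both have estimates.

## Environmental layer

**Humidity deficit.** HD = 217/(T+273.15) · 6.11·10^(7.5T/(T+237.3)) ·
(100−H)/100, in g·m⁻³ — the ideal-gas vapor-density factor times the Tetens
saturation vapor pressure (hPa) times the relative saturation gap. HD ≥ 0,
zero exactly at H = 100, strictly increasing in T below saturation.

**Daytime means and correlations.** Weather factors are averaged over
8:00–15:00 inclusive per date; Pearson r with the two-sided p from
t = r√((n−2)/(1−r²)) on n−2 df. Missing windows propagate as missing with
reduced n; gaps in the logger series are never imputed.

**Sensitivity scan.** For each clock time g on a 10-min grid, the
temperature is averaged over the right-closed trailing window (g−60 min, g]
— 6 records on a clean grid — per date, and correlated with FOT across
dates. The most negative r marks the temperature-sensitive phase of the
flower-opening program. P-values along the grid are reported raw (the scan
is descriptive); a Holm option exists in the statistics layer for callers
who want it.

**Drop triggers.** A day is *hot* when its full-calendar-day maximum
temperature strictly exceeds 35 °C (the daily maximum, not the daytime-mean
window, is what heat-stress classification refers to). The estimated FOT is
aligned to the nearest weather record (ties → earlier), and at each offset
ρ in −120…+30 min the day counts as a drop day iff the one-step 10-min
temperature difference at FOT+ρ is strictly below −0.5 °C. Fractions are
reported per day class with class sizes. The offset axis is FOT-relative by
default (the clock-time reading of "each time point" is available by
passing a constant FOT).

**Group comparisons.** Two-sided Wilcoxon rank-sum (Mann–Whitney) for every
group pair with Holm adjustment across pairs, returned as a symmetric
p-value matrix with unit diagonal.

## Synthetic study generator

The generator emulates the campaign's study conditions: 20-day campaigns,
frames 6:00–18:00 at 10-min intervals, true FOTs drawn uniformly over
9:00–14:30 (the observed anthesis range of *indica*/*japonica* material),
Poisson(15) flowers per day-side, opening times Gaussian around the true
FOT with SD 20 min (the ~30-min opening duration scale), box sizes bounded
so true-flower areas stay below the 6000 px cut, and labeled confounders:
shadow-colored boxes (b ≈ 120) with high scores, and yellow boxes with
scores in (0.5, 0.7). Weather is a diel sinusoid peaking at 14:00 with
AR(1) noise (coefficient 0.8 at the 10-min lag, innovation SD chosen so
spurious >0.5 °C/10 min drops essentially never occur) plus explicitly
injected dips recorded in the truth log; humidity is anti-phased and
radiation a daylight half-sine. Rendered scenes are flat-colored rectangles
on a dark backdrop — they exercise geometry, color conversion and
filtering, not the appearance variability a learned detector faces.

What passing tests therefore show: the post-detector pipeline (filtering,
index, spline peak, environmental statistics) is correct and recovers known
ground truth under realistic sampling noise. What they do not show:
detector accuracy on real imagery, robustness to lighting or occlusion, or
the field values of the environmental correlations — those depend on the
detector and campaign data.

Because the mock detector reports split boxes at tile boundaries (no
merging, by design), geometry recovery is scored by pixel-mask IoU between
a planted box and the union of intersecting detections.

## Problem sizes

Tests and the acceptance script run campaigns of 10–20 days with
Poisson(15) detections per day-side, the scale at which the estimator's
error statistics stabilise; rendered-image checks use a handful of frames
since rendering and color conversion dominate cost while adding no
statistical information.

## Known limitations

- The ONNX adapter follows the standard anchor-free single-output decode
  plus greedy NMS; it requires the optional onnxruntime dependency and is
  exercised only for its error paths in the default suite.
- Naive local timestamps throughout; campaigns spanning DST changes are out
  of scope.
- The generator draws each day's true FOT independently, so its
  neighboring-day FOT differences are larger than a weather-driven campaign
  would produce; the neighboring-day statistic is validated arithmetically,
  not distributionally.
- Correlated factors (temperature/radiation/humidity) are reported
  separately; no causal attribution is attempted.
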