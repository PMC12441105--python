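"""Run the mock detector over a rendered composite scene.

Renders one 2800x2800 frame with yellow flower boxes and dark shadow
confounders, tiles it 4x4 for detection, remaps boxes back to composite
coordinates, and shows the color filter removing the shadows.
"""

from datetime import date, datetime, time

import pandas as pd

from fotscope import synthfield as sf
from fotscope.detector import detect_frame
from fotscope.filterchain import apply_filters
from fotscope.tiler import CompositeRoi

day = date(2022, 8, 16)
ts = datetime.combine(day, time(11, 40))
cfg = sf.SceneConfig(
    fot_profile={(day, "left"): 11 + 40 / 60, (day, "right"): 11 + 40 / 60},
    fot_sigma_min=0.0,
    flowers_per_day_override={day: 6},
)
detections, _ = sf.generate_detections(cfg, seed=9)
shadows = pd.DataFrame(
    {
        "timestamp": ts,
        "x_min": [200, 950, 2300],
        "y_min": [400, 1800, 700],
        "x_max": [290, 1030, 2390],
        "y_max": [470, 1870, 790],
        "is_true": False,
    }
)
at_frame = pd.concat([detections[detections.timestamp == pd.Timestamp(ts)], shadows])
print(f"planted at {ts:%H:%M}: {int(at_frame.is_true.sum())} flowers, "
      f"{int((~at_frame.is_true).sum())} shadows")

composite = sf.render_composite(at_frame)
found = detect_frame(composite, ts, CompositeRoi(0, 0))
kept, rejected = apply_filters(found)
print(f"mock detector found {len(found)} boxes")
print(f"filter kept {len(kept)} (mean b of kept: {kept.mean_b.mean():.0f}; "
      f"rejected shadows have b < 140)")
# Kept boxes are the yellow flower regions; every dark shadow box fails the
# mean-b > 140 color criterion and is dropped with reason 'b'.
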