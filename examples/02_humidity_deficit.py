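"""Humidity deficit from temperature and relative humidity.

HD is the water-vapor mass (g/m^3) the air could still absorb before
saturating — the drying power a transpiring floret experiences.
"""

from fotscope.envstats import humidity_deficit

print("T(degC)  RH(%)  HD(g/m^3)")
for T, H in [(25.0, 50.0), (30.0, 50.0), (35.0, 50.0), (30.0, 80.0), (30.0, 100.0)]:
    print(f"{T:6.1f}  {H:5.0f}  {humidity_deficit(T, H):8.2f}")
# HD rises with temperature (more capacity) and falls with humidity,
# reaching exactly zero at saturation.
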