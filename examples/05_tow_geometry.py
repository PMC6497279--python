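"""Layback correction and swept-area arithmetic for towed gear.

A towed sled trails the vessel by sqrt(R^2 - D^2) for cable out R and depth
D; on meridional tows the correction applies to latitude only.
"""

from towcam.geometry import TowFix, correct_position, layback, swept_area

L = layback(cable_out_m=100, depth_m=26.5)
print(f"layback for 100 m cable at 26.5 m depth: {L:.1f} m")

fix = TowFix(vessel_lat=38.30, vessel_lon=-74.70,
             cable_out_m=100, depth_m=26.5, heading="north")
lat, lon = correct_position(fix)
print(f"vessel at ({fix.vessel_lat:.5f}, {fix.vessel_lon:.2f}) "
      f"-> sled at ({lat:.5f}, {lon:.2f})")

area = swept_area(width_m=1.83, speed_ms=1.0, duration_s=600)
print(f"one 10-minute beam-trawl tow sweeps {area:.0f} m^2; "
      f"15 stations sweep {15 * area:.0f} m^2")
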