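"""Sun event times, the day/twilight/night partition, and sun anchoring.

Computes the four sun events for an equatorial site, classifies a few
instants, and shows the double-anchoring transform that places sunrise
at pi/2 and sunset at 3*pi/2 regardless of site or season.
"""

import numpy as np

from dielkit import solar

LAT, LON = -3.0, -60.0  # central Amazonia

st = solar.sun_times(LAT, LON, "2021-03-20")
print(f"Sun events at ({LAT}, {LON}) on {st.date} (local civil time):")
for name in ("nautical_dawn", "sunrise", "sunset", "nautical_dusk"):
    print(f"  {name:>14}: {getattr(st, name).strftime('%H:%M:%S')}")

print("\nDiel classification (day = [sunrise, sunset); twilight flanks it; night is the rest):")
for t in ("2021-03-20 05:45", "2021-03-20 12:00", "2021-03-20 18:20", "2021-03-20 23:00"):
    print(f"  {t} -> {solar.classify_diel(t, LAT, LON)}")

print("\nSun-anchored circular time (radians; pi/2 = sunrise, 3pi/2 = sunset):")
for t in (st.sunrise, st.sunset, st.sunrise + (st.sunset - st.sunrise) / 2):
    theta = solar.anchor_to_sun(t, LAT, LON)
    print(f"  {t.strftime('%H:%M:%S')} -> {theta:.4f} rad ({theta / np.pi:.2f} pi)")

# The transform is invertible: angles map back to clock time to sub-second error.
theta = solar.anchor_to_sun("2021-03-20 15:30", LAT, LON)
back = solar.sun_to_clock(theta, LAT, LON, "2021-03-20")
print(f"\nRound trip: 15:30:00 -> {theta:.4f} rad -> {back.strftime('%H:%M:%S')}")
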