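"""Estimate the blood volume irradiated in a mouse ear for three beam timings.

The static volume is the blood held in the traced vessels inside the
6.5 x 6.5 mm field (cylinders in three diameter classes); the flow volume is
what four entry veins (0.09 mm, 2 mm/s) exchange while the beam is on.  The
mean dose to blood is diluted by the exchange: D_blood = D x V_static/V_irr.
"""

from flashear import (
    EntryVein,
    FlowParameters,
    VesselSegment,
    duration_for_dose,
    estimate,
    total_blood_volume,
)

segments = [
    VesselSegment("thick", "thick", 16.0),    # mm of thick vessel (d = 0.09 mm)
    VesselSegment("middle", "middle", 26.0),  # d = 0.05 mm
    VesselSegment("thin", "thin", 38.0),      # d = 0.04 mm
]
veins = [EntryVein(f"v{i}", 0.09) for i in range(4)]
total_ml = total_blood_volume(body_weight_g=19.2)  # 10.35 ml / 100 g
print(f"total blood volume of a 19.2 g mouse: {total_ml:.2f} ml\n")

for mode, rate in (("Flash930", 930.0), ("Flash9", 9.3), ("Conv", 0.06)):
    t = duration_for_dose(33.0, rate)
    est = estimate(segments, veins, FlowParameters(2.0, t),
                   total_dose_gy=33.0, total_blood_ml=total_ml)
    print(
        f"{mode:>8}: t = {t:8.3f} s   V_irr = {est.irradiated_volume_ul:7.3f} ul   "
        f"fraction = {est.blood_fraction_pct:6.3f} %   "
        f"mean blood dose = {est.mean_blood_dose_gy:5.2f} Gy"
    )

print(
    "\nAt ultra-high dose rate the exchange is negligible (V_irr ~ V_static,"
    " full 33 Gy to ~0.01 % of the blood); at the conventional rate >100x"
    " more blood is irradiated but each parcel receives only ~0.24 Gy."
)
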