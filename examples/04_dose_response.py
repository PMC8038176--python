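"""Dose-response reduction: percent growth and GI50 interpolation.

Optical densities from a viability assay reduce to percent growth (PG);
GI50 is where PG crosses 50%, interpolated linearly in log10(dose)
between the bracketing test concentrations.
"""

from dascreen import DoseResponseCurve, gi50_interpolate, percent_growth

od_tzero, od_ctr = 0.20, 0.85
measurements = [  # (concentration uM, OD after 48 h)
    (0.02, 0.82), (0.2, 0.75), (2.0, 0.50), (20.0, 0.24),
]

points = []
for conc, od in measurements:
    pg = percent_growth(od, od_tzero, od_ctr)
    points.append((conc, pg))
    print(f"{conc:6.2f} uM  OD {od:.2f}  PG {pg:6.1f} %")

result = gi50_interpolate(DoseResponseCurve(tuple(points)))
print(f"GI50 = {result} uM")

# The crossing lies between 2 and 20 uM; an all-above-50 curve would
# print the sentinel 'GI50 > 20' instead of a number.
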