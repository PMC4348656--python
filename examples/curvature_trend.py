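"""Curvature-hydrophobicity regression on a five-vesicle series.

Given hydrophobic surface fractions for vesicles of increasing diameter,
regresses the fraction against the diameter and against its reciprocal
(the curvature).  Surface hydrophobicity from packing defects scales with
curvature, so the 1/D regression is the near-perfect linear fit.
"""

from lipocurv.sasa import curvature_trend

# equilibrated diameters (nm) and hydrophobic SASA fractions (%) of a
# relaxed CG POPC vesicle series
diameters = [12.2, 19.6, 26.0, 34.4, 42.0]
fractions = [12.9, 9.2, 8.0, 7.4, 7.3]

out = curvature_trend(diameters, fractions)
for key, label in (("vs_diameter", "fraction ~ D  "), ("vs_reciprocal", "fraction ~ 1/D")):
    r = out[key]
    print(f"{label}:  r = {r.r:+.4f}  p = {r.p:.2e}  slope = {r.slope:+.3f}")
print(f"strictly decreasing with diameter: {out['monotone_decreasing']}")
print("\nthe 1/D fit (r ~ 0.99) shows hydrophobicity is linear in curvature;")
print("the direct-D fit is visibly worse (|r| ~ 0.87) because the decline saturates")
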