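"""Molar mass and shape anisotropy from sedimentation-velocity output.

Converts a c(s) peak position s_20,w and frictional ratio f/f0 into the
species molar mass (Svedberg + Stokes relation) and the bare prolate axial
ratio (hydration-stripped Perrin inversion).
"""

import aucsas

solvent = aucsas.SolventConditions(vbar=0.735)  # water at 293 K

s20w, ff0 = 4.31, 1.30  # a BSA-like monomer peak
mass = aucsas.molar_mass_from_sedimentation(s20w, ff0, solvent)
p = aucsas.axial_ratio_from_friction(ff0, hydration=0.3, solvent=solvent)

print(f"s_20,w = {s20w} S, f/f0 = {ff0}")
print(f"molar mass M = {mass / 1e3:.1f} kDa")
print(f"prolate axial ratio p = {p:.2f} (after stripping 0.3 g/g hydration)")

# doubling s at fixed f/f0 scales M by 2^(3/2): the closed form is
# homogeneous of degree 3/2 in both arguments
m2 = aucsas.molar_mass_from_sedimentation(2 * s20w, ff0, solvent)
print(f"check: M(2s)/M(s) = {m2 / mass:.4f} (= 2^1.5 = {2**1.5:.4f})")
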