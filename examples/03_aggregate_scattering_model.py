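"""The decoupling aggregate model against its brute-force oracle.

For a trimer of randomly arranged ellipsoidal subunits, compares the
closed-form decoupled profile i_3(q) = i_1(q)[1 + beta(q)(T_3(q) - 1)]
with a direct ensemble average over explicit random-flight chains.
"""

import numpy as np

import aucsas

rg1, p = 27.0, 1.5
shape = aucsas.SubunitShape.from_rg(rg1, p)
scenario = aucsas.SyntheticScenario(
    monomer_shape=shape,
    species_fractions={1: 0.5, 3: 0.5},
    concentration=2.0,
    monomer_mass=66.5e3,
    q_grid=np.geomspace(0.008, 0.25, 60),
    noise_level=0.0,
    seed=0,
)

_, oracle = aucsas.oracle_mixture(scenario, n_samples=50_000)
i1 = aucsas.monomer_curve(scenario)
model = aucsas.build_aggregate_model(scenario.q_grid, [1, 3], rg1, p)
i3 = aucsas.aggregate_profile(i1, 3, model)

mask = scenario.q_grid * rg1 <= 3.0
rel = np.abs(i3.intensity - oracle[3]) / oracle[3]
print(f"subunit: ellipsoid Rg = {rg1} A, axial ratio p = {p}; "
      f"chain step D = 2 Rg = {model.neighbor_distance:.0f} A")
print(f"T_3(0) = {model.t_factors[3][0]:.3f} (-> 3 at q = 0, forward "
      f"intensity of a trimer is 3x the monomer's)")
print(f"beta at q = 0.1 1/A: {model.beta[np.searchsorted(model.q, 0.1)]:.3f} "
      f"(1 would mean an isotropic subunit)")
print(f"max relative deviation from the 50k-chain oracle for q*Rg <= 3: "
      f"{100 * rel[mask].max():.2f}%")
print("\nThe decoupled closed form reproduces the exact ensemble average "
      "to well under a percent in the regime the reconstruction uses.")
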