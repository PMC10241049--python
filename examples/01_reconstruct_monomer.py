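"""Reconstruct a monomer SAXS profile from an aggregate-contaminated one.

Builds a BSA-like synthetic solution with 20% (by weight) dimer+trimer
aggregates, then runs both the first (Guinier-connection) and improved
(aggregate-model division) reconstructions and compares them to the known
ground truth.
"""

import warnings

import aucsas

scenario = aucsas.bsa_like_scenario(ra=0.20, seed=1)
profile, species, truth = aucsas.make_dataset(scenario)

solvent = aucsas.SolventConditions()  # water at 293 K, vbar = 0.735
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # r_a = 0.2 prerequisite warnings
    species = aucsas.assign_association_numbers(species, solvent)
    first = aucsas.first_aucsas(profile, species)
    improved = aucsas.improved_aucsas(profile, species)

print(f"true monomer:    Rg1 = {truth['rg1']:.2f} A, "
      f"i1(0) = {truth['i1_zero']:.4f} cm^2/mg")
for res in (first, improved):
    print(f"{res.method:>8s} method: Rg1 = {res.rg1:.2f} +- {res.rg1_sd:.2f} A, "
          f"i1(0) = {res.i1_zero:.4f} cm^2/mg, "
          f"qc*Rg1 = {res.q_connect * res.rg1:.2f}, "
          f"iterations = {res.iterations}")

print(
    "\nThe first method joins the Guinier bridge outside its validity "
    "range (qc*Rg1 > 1.3) and overestimates Rg1 by a few percent; the "
    "improved method divides out the aggregate mixture factor S(q) first "
    "and recovers the true monomer size and forward intensity."
)
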