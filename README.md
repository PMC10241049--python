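# aucsas

Reconstruct the small-angle scattering (SAXS/SANS) profile of a protein
**monomer** from a measurement contaminated by oligomeric aggregates, using
the species distribution measured by sedimentation-velocity analytical
ultracentrifugation (AUC).

Even a few percent of aggregates by weight inflates the apparent radius of
gyration and distorts the low-*q* region of a scattering profile, and when
the fraction is small the contamination leaves no visible low-*q* upturn to
warn you.  If an AUC run of the same solution resolves the species — weight
fractions *r*<sub>j</sub>, sedimentation coefficients *s*<sub>20,w</sub>
and a frictional ratio *f*/*f*<sub>0</sub> — the monomer profile can be
recovered from the mixture arithmetically, without size-exclusion
chromatography coupling or re-purification.  This package is for SAS
experimenters (laboratory SAXS and SANS included) who have such paired
measurements, and for methods developers who want a fully synthetic,
oracle-checked test bed for aggregate-correction procedures.

## Method

The measured absolute profile of a dilute mixture of a monomer and its
*j*-mers is

```
I(q) = c Σⱼ rⱼ i_j(q),            i_j = I_j / c_j,  rⱼ = c_j / c .
```

Two reconstructions of `i₁(q)` are implemented:

**First method** (Guinier connection).  Aggregates share the monomer's
local structure, so at high *q* the normalized profiles coincide and
`I₁H(q) = r₁ I(q)`.  The forward intensity follows from AUC masses,
`I₁(0) = I(0) r₁M₁ / Σⱼ rⱼMⱼ`, with `Mⱼ` from the Svedberg relation

```
M = [ s (f/f₀) 6πη (3v̄/4π)^⅓ N_A^⅔ / (1 − v̄ρ) ]^{3/2} .
```

The two pieces are bridged by a Guinier curve
`I₁(0) exp(−q²R_g1²/3)` joined smoothly (value and slope in ln *I* vs
*q*²) at a connection point *q*<sub>c</sub>.  With more than ~10%
aggregates the joint is forced outside the Guinier region
(*q*<sub>c</sub>·*R*<sub>g1</sub> > 1.3) and *R*<sub>g1</sub> comes out a
few percent high.

**Improved method** (aggregate-model division).  A *j*-mer is modelled as
*j* identical ellipsoidal subunits whose centres form a random-flight
chain with step *D* = 2*R*<sub>g1</sub> and whose orientations are
uncorrelated with their positions (decoupling approximation):

```
i_j(q) = i₁(q) [1 + β(q) (T_j(q) − 1)] ,
T_j(q) = 1 + (2/j) Σ_{m=1}^{j−1} (j−m) [sin(qD)/(qD)]^m ,
β(q)   = ⟨F(q)⟩² / ⟨|F(q)|²⟩ ,
```

where *F* is the form-factor amplitude of an ellipsoid of revolution with
axial ratio *p* obtained from *f*/*f*<sub>0</sub> by hydration-stripped
Perrin inversion.  The measurement is then divided by the mixture factor
`S(q) = Σⱼ rⱼ[1 + β(q)(T_j(q) − 1)]` before connecting, which
extrapolates correctly into the Guinier region; since *R*<sub>g1</sub>
enters *S*, the reconstruction iterates from the first-method estimate to
self-consistency (typically 4–5 rounds).

The package also provides a regularized indirect Fourier transform
(non-negative *P*(*r*) with smoothness penalty, χ²-plateau *D*<sub>max</sub>
scan), a coordinate-based electron-weighted *R*<sub>g</sub> for crystal-
structure reference values, and a synthetic-data module whose brute-force
oracle averages explicit random-flight chains with no decoupling
approximation — the independent truth every stage is tested against.

## Worked example

```python
import aucsas, warnings

scenario = aucsas.bsa_like_scenario(ra=0.20, seed=1)   # 20% aggregates
profile, species, truth = aucsas.make_dataset(scenario)

solvent = aucsas.SolventConditions()
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    species  = aucsas.assign_association_numbers(species, solvent)
    first    = aucsas.first_aucsas(profile, species)
    improved = aucsas.improved_aucsas(profile, species)
```

Running `python examples/01_reconstruct_monomer.py` (the script above)
prints:

```
true monomer:    Rg1 = 27.00 A, i1(0) = 0.0466 cm^2/mg
   first method: Rg1 = 28.36 +- 0.01 A, i1(0) = 0.0464 cm^2/mg, qc*Rg1 = 2.23, iterations = 1
improved method: Rg1 = 27.10 +- 0.09 A, i1(0) = 0.0464 cm^2/mg, qc*Rg1 = 0.34, iterations = 5
```

The first method's joint lands at *q*<sub>c</sub>·*R*<sub>g1</sub> = 2.2,
well outside the Guinier region, and overestimates the monomer size by
5%; the improved method recovers the generating *R*<sub>g1</sub> = 27 Å
and forward intensity to well under a percent.  The other scripts in
`examples/` demonstrate the Svedberg mass/shape conversions, the aggregate
scattering model against its chain-ensemble oracle, and the *P*(*r*)
analysis.

A thin command-line interface wraps the same calls:

```
aucsas simulate --ra 0.2 --seed 1 --out sim/
aucsas run --sas sim/profile.dat --species sim/species.csv --conc 2.0 --out out/
aucsas pr --sas out/monomer_profile.dat
aucsas massfroms --s20w 4.31 --ff0 1.30
```

`run` writes the monomer profile (3-column `.dat`), the *P*(*r*) curve, a
JSON report and a log.

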