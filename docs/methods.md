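# Methods

This note records the models, numerical choices and open design decisions
behind `aucsas`, and what the synthetic validation does and does not
establish about real data.

## Mixture model and its assumptions

The solution is treated as a dilute, interference-free mixture of a
monomer and its *j*-mers (*j* ≤ 4 assumed after ordinary purification;
total aggregate weight fraction *r*<sub>a</sub> = 1 − *r*<sub>1</sub>
below 0.2).  Both reconstructions consume the same AUC observables: the
weight fractions *r*<sub>j</sub> (from c(s) peak areas), the sedimentation
coefficients *s*<sub>20,w,j</sub>, and one shared frictional ratio
*f*/*f*<sub>0</sub>.  Violations of the prerequisites (a pentamer peak, or
*r*<sub>a</sub> > 0.2) produce warnings, never errors: the arithmetic
still runs, the user decides.

Species masses come from the Svedberg/Stokes closed form
`M = [s (f/f0) 6πη (3v̄/4π)^{1/3} N_A^{2/3} / (1 − v̄ρ)]^{3/2}` (CGS, s in
seconds), which is homogeneous of degree 3/2 in both *s* and
*f*/*f*<sub>0</sub>; association numbers are `round(M_j/M_1)` clipped to
≥ 1, because the inter-subunit structure factor needs an integer *j* while
the forward-intensity weighting uses the measured masses as they are.

## Aggregate scattering model

A *j*-mer is *j* identical subunits at random-flight chain positions
(step *D*, no excluded volume) with orientations independent of positions.
Under that ensemble the decoupling factorization

`i_j(q) = i_1(q)[1 + β(q)(T_j(q) − 1)]`

is exact, with `T_j` the chain-ensemble average of the Debye double sum
(closed form above) and `β = ⟨F⟩²/⟨|F|²⟩` the subunit anisotropy.  The
model's approximations relative to *real* aggregates are therefore (i) the
random-flight geometry itself (real subunits touch; chains here may
overlap), (ii) orientational independence, and (iii) the ellipsoidal
subunit.  The synthetic oracle can probe (i) and (ii) through its
`min_separation` and `correlated_orientations` options.

The subunit is an ellipsoid of revolution with semi-axes (*pr*, *r*, *r*).
Its axial ratio comes from the frictional ratio by first stripping
hydration, `(f/f0)_shape = (f/f0)/(1 + δ/(v̄ρ))^{1/3}` with δ = 0.3 g/g by
default (textbook protein hydration; overridable), then inverting the
prolate Perrin factor `F_P(p) = p^{-1/3}√(p²−1)/ln(p+√(p²−1))` by
bracketed root finding on [1+10⁻⁶, 100].  The prolate branch is the
standard convention for globular-protein AUC shape analysis and makes the
inversion single-valued; an oblate variant is exposed.  When the stripped
ratio does not exceed 1, p = 1 is returned.  The subunit semi-axis is set
so the ellipsoid's R<sub>g</sub> equals R<sub>g1</sub>
(`r = R_g1 √(5/(2+p²))`), and the chain step is fixed at
D = 2R<sub>g1</sub> — the subunit's effective diameter — with an override
for sensitivity studies.

Orientational averages use 128-point Gauss–Legendre quadrature in
cos α on [0, 1] (relative accuracy beyond 10⁻¹⁰ for *qr* ≤ 50); the
spherical kernel `3(sin u − u cos u)/u³` switches to its 6th-order series
below |u| = 10⁻², where both branches agree to ~10⁻¹³.

Two properties of the model worth stating precisely, because idealized
versions of them circulate: `T_j(q)` dips slightly below 1 past the first
sinc zero (e.g. `T_2 = 1 + sinc(qD)` on qD ∈ (π, 2π)), and the mixture
factor's high-*q* decay is set by the sinc envelope — for the default
BSA-like conditions |1/S − 1| is still ≈ 1.8% at qR<sub>g1</sub> ≈ 4.2 and
falls below 1% only beyond qR<sub>g1</sub> ≈ 5.5.

## Guinier connection

Given `I₁(0)` and a high-*q* estimate `I₁H`, the Guinier bridge
`G(q) = I₁(0) exp(−q²R²/3)` is a one-parameter family; demanding that it
pass through the (locally smoothed) data at a candidate joint q_c fixes
`R²(q_c) = 3[ln I₁(0) − ln I₁H(q_c)]/q_c²`, so a *smooth* joint needs only
the local slope of ln I vs q² to agree with −R²/3.  The connection point
is the smallest data point where the relative slope discontinuity falls
below 0.05, subject to three robustness rules: the local slope (from a
±5-point weighted fit) must actually be measurable (standard error below
0.25 in relative units), the tolerance widens to twice the slope's
standard error where the data are noisy, and three consecutive points must
agree so a single fluctuation cannot fake a joint.  If no candidate
achieves a discontinuity below 1, the inputs are declared mutually
inconsistent and an error is raised.  The final R<sub>g1</sub> and its
standard deviation come from a weighted Guinier refit of the connected
profile over qR<sub>g1</sub> ≤ 1.3 (the conventional validity cap,
configurable), iterated on its own window.

Two consequences are worth knowing.  First, a weighted Guinier fit over
the full qR<sub>g</sub> ≤ 1.3 window of an exactly known body is itself
biased by the window (about +1.7% for a sphere with constant-relative
errors, +0.6% with the noise model below) — this is a property of Guinier
analysis, not of the connection.  Second, at high signal-to-noise even a
6% aggregate fraction produces a many-σ excess at low *q*, so the joint is
correctly postponed and the first method shows a measurable positive bias
there too; the first method is only as good as the noise that hides the
contamination.

The improved method recomputes S(q) with the current R<sub>g1</sub>
(D = 2R<sub>g1</sub>, subunit re-scaled), divides, reconnects, and
iterates to |ΔR<sub>g1</sub>|/R<sub>g1</sub> < 10⁻³ (max 20 rounds;
typically 4–5).  `I₁(0)` is computed once from the total-profile Guinier
extrapolation and the AUC mass weighting; when `M_j = j M_1` exactly it
coincides with the q→0 limit of `r₁ I(0)/S(0)` to machine precision, which
is asserted in the tests.

## Indirect Fourier transform

P(r) is represented on a 121-point grid over [0, d_max] with pinned
endpoints and fitted through the Debye integral by error-weighted
**non-negative** least squares with a second-difference smoothness
penalty.  Non-negativity is enforced inside the active-set solve rather
than by clipping afterwards: on aggregate-contaminated or truncated data
the unconstrained solution fits well with large signed oscillations, and
clipping such a solution destroys the fit entirely.  The regularization
weight defaults to the largest λ whose χ² stays within a small slack
(5% relative, 0.02 per point absolute) of the best achievable — the
smoothest distribution still consistent with the data.

`estimate_dmax` scans candidate d_max values and returns the smallest one
on the χ² plateau (within 5%, with an absolute slack of 0.5 in reduced
units so a numerically perfect fit does not disqualify its neighbours)
whose P(r) does not press against the outer boundary (P beyond 0.95 d_max
under 20% of the peak).  A profile whose best fit exceeds χ²/N = 10, or a
scan with no interior plateau, raises an error.  Note the information
limit: the outermost few percent of a particle's P(r) carries so little
mass that truncating it changes the model by far less than any realistic
error bar, so recovered D_max values approach the geometric maximum from
below (for a p = 2 ellipsoid the estimate sits ~10% short of 2pr at any
finite noise).

## Synthetic data and what passing tests mean

The generator's defaults are the study conditions: a BSA-like monomer
(R<sub>g1</sub> = 27 Å, M₁ = 66.5 kDa, i₁(0) = 7×10⁻⁷·M₁ cm²/mg), total
concentration 2.0 mg/ml, fractions 0.80/0.14/0.06 for monomer/dimer/trimer
(r_a = 0.20), 120 log-spaced q points on [0.008, 0.25] Å⁻¹, and Gaussian
noise σ(q) = 0.005·I(0)·(1 + q/q_max).  The default subunit axial ratio is
p = 1.5: modest anisometry inside the p ≤ 2 regime for which the
decoupling error bounds are validated (the hydrated Perrin map then emits
f/f₀ ≈ 1.14 into the species table, and the reconstruction recovers p
exactly by the inverse map).  Sedimentation coefficients are generated by
the forward Svedberg relation so the AUC side of the pipeline is
self-consistent by construction.

The oracle averages |Σ_k F_k e^{iq·R_k}|² over explicit chains, fresh
subunit orientations and random q directions — no decoupling — so
closed-form-vs-oracle agreement (≤ 0.4% for qR<sub>g1</sub> ≤ 3, p ≤ 2,
j ≤ 4 at 10⁵ samples) validates the algebra, *and* the full-loop recovery
(R<sub>g1</sub> within 1%, i₁(0) within 2%, mean over ten seeds) validates
the inversion under noise.  What these tests do **not** establish: recovery
when real aggregates violate the random-flight geometry (compact tetramers,
touching subunits, correlated orientations), when f/f₀ mixes species
shapes, or when the instrument introduces smearing or incoherent
background — none of which the generator emulates.  The stress-test
options (`min_separation`, `correlated_orientations`) exist to explore the
first of these.

## Degenerate inputs and tie-breaks

Profiles: q ≤ 0 rows dropped, duplicate q merged by inverse-variance
weighting, a missing σ column synthesized as max(1% of I, 10⁻³ of the
smallest positive I).  Species tables: fractions renormalized with a
warning when off unity by < 10⁻³, rejected beyond that; the monomer is
whichever species sediments slowest.  The Guinier auto-window widens
(doubling) when its initial points show a noise-flat slope.  Tiny
aggregate fractions are retained, never pruned.  All randomness flows
through explicit integer seeds.

## Known limitations

* The connection-point rule's constants (slope tolerance 0.05, ±5-point
  smoothing, 3-point run) were chosen for the laboratory-SAXS-like noise
  regime; extremely sparse grids or very smooth oversampled data may merit
  adjusting them.
* The shared f/f₀ is applied to all species, as the AUC analysis that
  produces it assumes.
* β(q) uses a single effective ellipsoid; strongly non-ellipsoidal
  monomers (p implied > 2) leave the validated regime, though the error
  enters only through the aggregate correction term, which is itself
  O(r_a).
* Absolute-scale calibration, buffer subtraction, smearing and
  concentration-series extrapolation are upstream of this package.
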