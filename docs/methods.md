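# Methods

This note records the scientific and numerical choices behind
`stillref`: the partiality model, the scaling/merging and refinement
procedures, what the simulator does and does not emulate, and the
decisions taken where the design was genuinely open.

## Geometry and units

Reciprocal space is handled in nm⁻¹ throughout; wavelengths enter in
ångström and are converted at module boundaries (E[keV]·λ[Å] =
12.39842). The beam travels along +z and the nominal Ewald sphere of
radius 1/λ is centred at (0, 0, −1/λ), so the reciprocal-space origin
lies on it. A crystal's cell and orientation are carried jointly as the
nine Cartesian components of a*, b*, c* (columns of a 3×3 matrix, flat
order a*x … c*z); these nine numbers are also the refinement
parameters. Orientations are drawn Haar-uniformly via unit quaternions
(`scipy.spatial.transform.Rotation.random`).

The simulator indexes on the *primitive rhombohedral* lattice
(a = 144.2 Å, α = 113.78°) and merges in the Laue group of point group
32, built from gemmi's space-group operators plus the inversion
(order 12, so Friedel mates merge; an identity-only group or any
explicit operator list can be configured instead). The hexagonal
(obverse) setting is available on `UnitCell` for bookkeeping, but
simulating on it would triple the lattice and require systematic-absence
handling for no statistical gain — every quantity computed here is
setting-independent.

## Partiality model

Each reciprocal-lattice point carries a sphere of scattering density of
radius r = 5×10⁻³ nm⁻¹ (a model constant, configurable). The spectral
top-hat (full fractional width 5×10⁻⁴) and the convergence cone (full
angle 10⁻³ rad) generate a nest of Ewald spheres. The nest is sampled
at its four extreme members — two wavelength extremes crossed with the
incident beam tilted by ±γ/2 *in the plane containing the beam axis and
the scattering vector*. In-plane tilt extremizes the radial excitation
distance over the tilt cone, so these four spheres bound the nest
exactly to first order; the envelope property also means the gradients
may hold each extreme sphere's centre fixed, which the
finite-difference oracle confirms to ~10⁻⁸ relative.

For each extreme sphere (centre c, radius R) the signed distance is
e = R − |s − c|: negative when the sphere surface lies closer to the
Ewald centre than the point, as the sign convention requires.
r_high = min e, r_low = max e. Because r (5×10⁻³ nm⁻¹) is three orders
of magnitude below the Ewald radius (~6.45 nm⁻¹), the two limiting
surfaces are treated as parallel planes across the reflection sphere,
and the excited volume fraction is a difference of spherical-cap
fractions, p = f(r_high) − f(r_low) with f(t) = (r−t)²(2r+t)/4r³ after
clamping both distances to [−r, r]. Note f′(±r) = 0, so p is C¹ across
the clamping boundary and a clamped bound contributes an exactly zero
gradient — the clamp bookkeeping and the calculus agree.

The Lorentz factor uses the *unclamped* distances, L = k_L/(r_low −
r_high); clamped distances would make L depend on p, mixing the two
corrections. Only the proportionality is physical; k_L is normalized to
the nest thickness at the detector-edge resolution (L = 1 at d = 2.41 Å
on the nominal sphere), and any constant choice is absorbed by the
per-pattern scales. For thin centred slabs p·L is independent of slab
thickness to O((t/r)²) — the compensation that makes a barely-excited
low-angle reflection and a nearly-fully-excited one appear with similar
intensities. The compensation is only approximate for truly fully
recorded reflections (exact equality would require a slab of thickness
4r/3, which does not fully contain the sphere), matching the
qualitative "approximately equal" character of that argument.

## Simulator

`simulate_dataset` produces, per pattern: a Haar-random orientation, a
scale G ~ N(1, 0.3) truncated to positive values (P(G≤0) ≈ 4×10⁻⁴
untruncated; resampling avoids unphysical negative scales), the
reflections whose spheres intersect the excitation shell *and* whose
diffracted beams hit the detector square (projection at the nominal
wavelength), partial intensities G·p·L·I_full + ε, and a working basis
with each component independently multiplied by (1 + u),
u ~ U(−0.001, +0.001) (or ±0.01 for the hard dataset).

Reference intensities are synthetic: acentric-Wilson (exponential)
draws with mean ⟨I⟩(s) = I₀·exp(−B s²/2), B = 50 Å² by default. The
value of B matters more than it may appear: the noise rule sets one
constant σ equal to the mean intensity of the highest-resolution shell
(20 equal-count shells of the reference table), so B fixes the
signal-to-noise profile of the entire dataset. B = 50 Å² is typical of
structure-factor sets calculated from a mid-resolution (~2.8 Å)
membrane-protein model — the kind of source data this simulation
protocol emulates — and yields a dataset whose resolution limit is set
by noise at the detector corner (d ≈ 1.93 Å) while low-resolution data
are strong. Negative noisy intensities are kept: clipping would bias
the merge of weak reflections.

The reference table (and the candidate index list) extends 2% past the
corner resolution so that every predictable reflection has a true
intensity; the candidate list is cached per cell since |s| is
orientation-invariant. Partiality statistics (dataset mean 0.244,
maximum 0.77 at 1000 patterns) are computed over all simulated
observations before any rejection.

What the simulator does *not* emulate: per-crystal variation of
diffraction strength, resolution or mosaicity; FEL spectral jitter
(every pattern sees the same top-hat); polarization; pixelated
detectors, spot shapes or integration errors; indexing ambiguities.
Passing tests therefore demonstrate the internal consistency and
stability of the method under its own model assumptions — the same
model generates and processes the data — not its performance on
experimental images.

## Scaling and merging

Full intensities are estimated as the unweighted mean of I/(G p L) over
all symmetry equivalents in all patterns (a 1/σ²-weighted variant is
available behind a flag), excluding p < 0.1. Scales are fitted by the
linear-cost iteration: merge with G = 1, fit each pattern's
G = Σ(I_full,e·Î)/Σ(Î²) against the merged table, normalize mean G to 1
(the gauge is arbitrary; the simulator draws G around 1), re-merge.
Production uses 3 rounds; convergence is geometric (~×0.9 per round),
so the noiseless-recovery test runs 200 rounds to reach its 10⁻⁶
tolerance. The p ≥ 0.1 cut applies inside the scale fit as well as in
merging, for consistency. There is no per-pattern B factor — one
overall scale per pattern is the model.

## Post-refinement

Residual per measurement: ΔI = I/(G·L) − p·I_full, unit weights
(a 1/σ² option exists); G is held fixed during the inner iterations and
re-fitted only at the next outer scaling step. Jacobian rows are
−I_full·∂p/∂v with ∂L/∂v ≡ 0. Selection: I ≥ 3σ, p ≥ 0.1, a merged
estimate exists, and at least one *other* scalable measurement of the
unique reflection anywhere in the dataset (multiplicity index built
once per cycle); an empty selection skips the pattern, which keeps its
basis and still contributes to merging. Selection is re-evaluated each
inner iteration from the current partialities.

The 9×9 Gauss–Newton system is rescaled by D = diag(1/√A_ii) so its
diagonal is 1 (zero-diagonal parameters are frozen with zero step) and
solved by SVD with singular values below 10⁻⁶ of the largest zeroed.
One eigenvalue is eliminated on essentially every full-size pattern:
rotation about the beam axis leaves all |s − c| and hence all
partialities unchanged, an exact one-dimensional null space. The step
never moves along eliminated directions (verified in the rescaled
metric to ~10⁻¹² cosine). No damping is used; the safeguards are
exactly the SVD filtering, the max|Δp| < 0.01 / 10-iteration stop, and
the revert rule: if a step assigns p = 0 to more than ⅓ of the selected
reflections it is rolled back and iteration stops (no step-halving —
reverting terminates the pattern's refinement for this cycle).

The outer driver is [scale+merge] then n_cycles × [refine every pattern
→ scale+merge], with n_cycles = 0 the "no refinement" baseline. Two
further baselines are built in: all partialities forced to 1 with the
Lorentz correction retained (Monte-Carlo-style merging), and all G = 1
(no scaling).

## Evaluation

The quality metric is the intensity R-factor against the generating
reference, R = Σ|I_m − k·I_ref| / Σ k·I_ref with one least-squares
scale k over all common reflections (gauge-consistent with the
simulator's arbitrary units), reported overall and in equal-count
resolution shells (default 10). Fig-2-style dataset statistics (count,
mean p, max p) use equal-width-in-1/d shells instead.

The "observed partiality" of a measurement is I/(G·L·Î) — corrected for
scale and Lorentz factor but not partiality — compared against the
calculated p. Because Î sits in the denominator and true intensities
are exponentially distributed with mass near zero, p_obs is heavy-tailed
(empirical values beyond ±10³), and a Pearson correlation over *all*
pairs is dominated by a handful of outliers at any dataset size. The
summary correlation is therefore computed over pairs whose estimate is
significant (≥2 contributing measurements and Î > 3× its standard
error); all pairs are returned, flagged, for plotting. On the
0.1%-error dataset this correlation rises from 0.67 to 0.86 after one
refinement cycle (1000 patterns).

## Behaviour at the two error levels

At ±0.1% initial basis errors (1000 patterns) three cycles reduce the
overall R from 0.077 to 0.018, the fitted scales correlate with truth
at 0.994, and 96% of patterns end closer (Frobenius) to their true
basis — the refinement genuinely recovers geometry. At ±1.0% the method
still improves the intensities substantially (R 0.25 → 0.078) and the
partiality correlation rises from 0.04 to 0.45, but the basis
*components* drift slightly away from truth (median error 0.0057 →
0.0080): with nearly uninformative starting partialities the ensemble
converges to a self-consistent geometry that reproduces the intensities
without matching the true parameters along weakly constrained
directions (the beam-axis rotation is exactly unconstrained; others are
nearly so). The merged intensities — the quantity the method exists to
deliver — improve in both regimes.

## Problem sizes in the tests

Unit tests run on a reduced detector (30 mm) that raises the corner
resolution to ~3.9 Å and cuts reflection counts ~15-fold while keeping
the full beam and crystal model. The dataset-statistics check uses 200
patterns; the processing-variant orderings, rank-deficiency and
scale-recovery checks use 300-pattern datasets at both error levels —
sizes at which every tested ordering holds with wide margins (e.g.
R: 0.020 < 0.038 < 0.123 < 0.55 on the 0.1% dataset). The acceptance
script runs the full 1000 patterns. Rank-deficiency statistics are
quoted on full-detector patterns; small-detector patterns can have
additional near-degenerate directions (few well-measured reflections)
and are not a valid substrate for that check.

## Known limitations

* The partiality model is shared between simulation and processing;
  model error on real data is unquantified here by construction.
* The four-sphere nest sampling is first-order exact for the extreme
  surfaces; strongly off-axis geometries with large convergence would
  need the full cone.
* Gauss–Newton without damping relies on the revert rule for stability;
  at ±1% starting errors a few hundred of 3000 pattern-cycles revert.
* Component-space geometry recovery degrades as starting errors grow
  (see above), even while merged intensities improve.
* The stream format is intentionally minimal (h k l I σ p L per line);
  it is "stream-like", not an interchange format with other software.
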