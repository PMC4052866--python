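# stillref

Partiality-aware scaling, merging and post-refinement for snapshot
("still") serial crystallography, with a built-in snapshot simulator.

## The problem

In serial femtosecond crystallography (SFX) every crystal yields exactly
one still diffraction pattern before being destroyed, in an orientation
unrelated to every other crystal. Without rotation, every reflection is
*partially* recorded: the detector sees only the fraction of each
reciprocal-lattice point that happens to intersect the thin shell of
reciprocal space excited by the beam. The common remedy — Monte-Carlo
merging, i.e. averaging many partial measurements per unique reflection
and hoping the partialities average out — needs enormous numbers of
patterns. If the partialities p could be *calculated* from the
diffraction geometry, each measurement could be corrected individually
("method of scaled partials") and far fewer patterns would suffice. The
catch: the geometry delivered by indexing is not accurate enough for
useful partiality estimates, and still data contain no fully recorded
reflections to refine it against.

`stillref` implements the resolution of this chicken-and-egg problem:
**post-refinement against the dataset's own merged intensities**,
iterated. For people working on SFX data processing it provides the
complete loop as a library and command-line tool, exercisable without
any external data through its simulator.

## Model and algorithm

Each reciprocal-lattice point carries a sphere of scattering density of
radius r. The beam's spectral bandwidth (top-hat, full fractional width
Δλ/λ) and convergence (full angle γ) generate a *nest* of Ewald spheres;
the excited region is bounded by the two extreme ("limiting") spheres.
Signed radial distances r_high ≤ r_low locate the two limiting surfaces
relative to the point centre (negative = surface closer to the Ewald
centre than the point), are clamped to [−r, +r], and give the partiality
as a difference of spherical-cap volume fractions:

    p = f(r_high) − f(r_low),      f(t) = (r − t)²(2r + t) / 4r³.

A Lorentz factor L ∝ (r_low − r_high)⁻¹ (from the unclamped distances)
undoes the spreading of incident intensity over the thicker excited
shell at high scattering angle. The forward model for a measurement e
in pattern j is then

    I_ej,partial = G_j · p_ej · L_ej · I_full(hkl),

with one scale factor G_j per pattern.

One processing cycle is:

1. **Scale & merge** (linear-cost iteration): merge with equal scales,
   fit each G_j to the merged table by least squares, re-merge, repeat a
   few times. Merging averages I/(G p L) over all symmetry equivalents,
   rejecting p < 0.1.
2. **Post-refine** each pattern: minimize Σ (I/(G L) − p·I_full)² over
   the nine Cartesian components of the reciprocal basis vectors
   (a*, b*, c*) by Gauss–Newton, using analytic ∂p/∂v (∂L/∂v ≡ 0,
   clamped bounds contribute zero). The normal equations are
   preconditioned so the diagonal is 1 (Bricogne rescaling) and solved
   by SVD, dropping eigenvalues below 10⁻⁶ of the largest — exactly one
   is dropped on a generic still pattern, because rotating the crystal
   about the beam axis changes no partiality. Iteration stops when
   max|Δp| < 0.01 or after 10 steps; a step that zeroes more than a
   third of the refined partialities is reverted.
3. Repeat from 1 with the refined geometry.

The simulator generates the complementary test bed: synthetic
Wilson-distributed full intensities on a rhombohedral lattice
(a = 144.2 Å, α = 113.78°, point symmetry 32, merged in the Laue group),
Haar-random orientations, an 8 keV beam (0.05% bandwidth, 1 mrad
convergence, r = 5×10⁻³ nm⁻¹), a 76.8 mm square detector at 50 mm,
per-pattern scales G ~ N(1, 0.3), flat-top basis errors (±0.1% or ±1%
per component) and constant Gaussian noise pegged to the mean intensity
of the highest-resolution shell.

## Worked example

A 150-pattern dataset at the default (full) configuration, processed
once without and once with post-refinement:

```
$ cat config.yaml
n_patterns: 150
$ stillref simulate --config config.yaml --out dataset --seed 11
150 patterns, 223505 observations, mean partiality 0.244, max 0.765
$ stillref merge --input dataset --config config.yaml --out merged0.hkl
merged 58015 unique reflections from 150 patterns
$ stillref evaluate --merged merged0.hkl --reference dataset/reference.hkl --shells 10
overall R = 0.1611 over 58015 reflections
$ stillref refine --input dataset --config config.yaml --cycles 3 --out merged3.hkl --report report.json
cycle 1: refined 150 patterns, 0 reverted
cycle 2: refined 150 patterns, 0 reverted
cycle 3: refined 150 patterns, 0 reverted
final merged table: 58743 unique reflections
$ stillref evaluate --merged merged3.hkl --reference dataset/reference.hkl --shells 10
overall R = 0.0261 over 58743 reflections
$ stillref diagnose --input dataset --config config.yaml --merged merged3.hkl --pairs pairs.csv
observed/calculated partiality correlation: 0.6711
```

Reading the numbers: the raw simulation has mean partiality 0.244 —
three quarters of every reflection's intensity is, on average, *not*
recorded. Scaling and merging with partialities calculated from the
(deliberately perturbed) indexing geometry reaches R = 0.16 against the
true intensities; three cycles of post-refinement drop this to
R = 0.026, a six-fold improvement obtained purely by refining nine
geometric parameters per pattern against the dataset's own consensus.
The diagnose step writes observed-vs-calculated partiality pairs — the
scatter practitioners plot to judge how well the partiality model
explains the data.

`evaluate` writes per-shell R-factors as CSV; `--report` captures
per-pattern refinement records (iterations, eliminated eigenvalues,
reverted steps).

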