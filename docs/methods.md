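# Methods

This note documents the models, conventions and numerical choices behind
`cellsolv`, and what the synthetic-data tests do and do not establish about
real molecular-dynamics data.

## Units and geometry

Distances in Å, time in ps, masses in amu, charges in e, energies in
kcal/mol, angles in degrees. Boxes are orthorhombic; all distances use the
orthorhombic minimum-image convention. Periodic neighbor queries go through
a k-d tree with periodic boxsize when the cutoff is below half the smallest
box edge, and fall back to exact minimum-image enumeration otherwise; the
two paths are property-tested to return identical pair sets, so the tree is
purely an acceleration.

## The synthetic bundle

`synthetic.build_ibeta_bundle` produces an idealized all-atom bundle with
the standard cellulose atom naming (C1–C6, O1–O6, H1–H5/H61/H62,
HO1/HO2/HO3/HO4/HO6) and 21·g + 3 atoms per g-glycan strand (terminal HO4
and O1/HO1 caps). Successive glycans follow a two-fold screw: a 5.19 Å
translation along the chain axis (half the 10.38 Å cellobiose repeat)
composed with a 180° rotation about it. Strands sit on integer (row, col)
cross-section sites, 8.2 Å apart within a hydrogen-bonded sheet and 3.9 Å
between stacked sheets — the published Iβ cell spacings.

The glycan template itself is *stylized*, not crystallographic: atom
positions were chosen so that, under the geometric bond criteria, every
glycosidic junction carries exactly the two primary intra-strand bonds
(O5⋯HO3-O3 and O6⋯HO2-O2), every in-row strand pair shares O3⋯HO6-O6
inter-strand bonds, and no unintended bond appears anywhere in the ideal
lattice (verified by the detector itself in the tests). A handful of
covalent bond lengths are therefore 0.95–1.7 Å rather than textbook
values; connectivity is carried explicitly by residue templates, never
inferred from distances, so this costs nothing downstream. Analyses that
depend only on bond topology, COM positions, torsions and counting are
exact on this geometry; absolute energies are not meaningful on it, which
is why the energy stage is validated by closed forms and all-pairs oracles
instead.

The default 18-strand cross-section is the 3-4-4-4-3 habit. The
cross-section classifier peels shells by erosion (boundary = fewer than
four orthogonal occupied neighbors): shell 1 splits into `corner` (convex
hull vertices) and `first_layer`; shell 2, when deeper shells exist, into
`above_corner` (adjacent to a corner) and `second_layer`; the innermost
shell is `center`. For shallow bundles like 18 strands this yields
corner/first-layer/center only — with three layers of strands there simply
is no distinct second layer. Both the layout and the class map can be
overridden. Mirror pairs reflect the layout about its vertical center
axis.

## Solvent and packing

Pseudo-TBP is a tetrahedral P with four all-anti butyl arms (53 atoms:
P + 16 C + 36 H, hydrogens named HP/HC2/HC3/HC4 by carbon position); only
its topology and rough sterics matter. Water is a rigid 3-site molecule
(Ow, Hw, Hw); chloride a single atom. Packing is rejection sampling with a
1.5 Å solvent–solvent clearance and a bounded retry budget (200 tries per
molecule, then a packing error reporting achieved counts) — not a physical
equilibration. After packing, any solvent molecule with an atom within
2 Å of cellulose is deleted, mirroring the void carved when a bundle is
inserted into a pre-equilibrated box; a post-condition scan in the tests
confirms no surviving violation.

## Kinematic peeling and the telegraph oracle

Peeling trajectories are kinematic, not dynamical. Displacement schedules
move a strand's glycans along a direction (default: outward from the
bundle centroid) with end-first weighting — weight 1 at the strand ends
falling linearly to 0 at the center, since chain ends detach first — and
twist schedules rotate each junction's distal segment about the current
C1–O4 glycosidic bond, proximal to distal, so every junction torsion
advances by exactly the scheduled angle (test-verified to 1 %). Isotropic,
per-atom, per-frame Gaussian jitter stands in for thermal motion; it is
uncorrelated in time and space, which is adequate for exercising
estimators and deliberately non-physical. Same seed ⇒ bitwise-identical
trajectories.

Bond telegraph processes alternate exponentially distributed bound/unbound
sojourns (starting bound) sampled on a uniform grid. Because exponential
sojourns are memoryless, the continuous-mode autocorrelation of a sampled
telegraph is exactly exp(−k·dt/τ) in expectation, making the telegraph a
closed-form oracle for the whole lifetime pipeline.

What passing these tests shows: the estimators recover planted structure
(bond networks, lifetimes, separations, slopes, torsions) correctly from
data with known truth. What they do not show: anything about force-field
accuracy, solvent structure, correlated dynamics, or real TBPCl–water
thermodynamics — those require actual MD trajectories.

## Hydrogen bonds

Criteria: d(H⋯A) ≤ 2.45 Å, angle ≤ 30°, d(D⋯A) ≤ 3.5 Å. The angle vertex
sits at the donor (∠ H–D–A) by default, matching the "hydrogen-donor–
acceptor" word order of the criterion's usual statement; since the
vertex-at-hydrogen convention also circulates, `angle_vertex="hydrogen"`
switches to deviation-from-linearity at H. The three thresholds are
mutually consistent: a grid search over admissible geometries with
d(D–H) = 1.0 Å caps the donor–acceptor distance at 3.45 Å ≤ 3.5 Å.

Default donors are O–H (cellulose hydroxyls, water); C–H donors exist in
the detector but are off by default for speed and enabled per-call for
anion–alkyl analyses. Acceptors are O and Cl. One hydrogen may bond
several acceptors simultaneously (chloride routinely holds multiple
bonds); no exclusivity is imposed. Per-glycan class averages normalize
primary intra-strand counts by g−1 (the last glycan has no junction
partner; 11 for 12-glycan strands) and all other classes by g; inter-strand
bonds count once for each participating strand. Pocket censuses count
molecules with atoms within the cutoff of *both* flanking strands, and the
exchange ratio is the time-averaged TBP:water pair rounded to one decimal
and reduced to the smallest integer ratio ("-" when empty).

## Lifetimes

Continuous (survival) mode is the default: time origins are bond-formation
events, C(t) is the fraction of origins whose bond persists unbroken
through lag t among origins with t observable, and τ is the trapezoidal
integral of C to its first decay to zero — operationalized as C ≤ 10⁻³ to
tolerate floating-point tails (configurable). Intermittent mode
(P(bound at t | bound at 0), all bonded samples as origins, FFT-evaluated)
is provided since either convention appears in practice; for exponential
sojourns both recover τ. Class averages pool numerators and denominators
across bonds (origin-weighted) before integrating, rather than averaging
per-bond τ values; the per-bond alternative is a one-line change on the
returned series list.

The cascade evaluates resolutions finest-first — 0.01 ps over a 100 ps
window, 0.1/1 000, 1/10 000, then 10 ps to the end of the run — and keeps
the first resolution whose C reaches zero inside its window; if none does,
the result is censored and rendered with a ">" prefix. Sample averaging
uses 10 windows of 80 % of the series with evenly spaced starts (requiring
≥ 10 distinct starts, i.e. at least 46 points); a censored sample censors
the average. Integrating to the *first* zero crossing makes the reported τ
non-decreasing in the window length, which the suite asserts as the
censoring-monotonicity property.

## Dissolution

Glycan COMs are mass-weighted with connectivity-based unwrapping inside
each glycan (reference atom + minimum-image offsets), so box-straddling
glycans keep physical COMs; strands are never unwrapped against each
other. NN(s,j) compares only same-numbered glycans across strands, ties
resolving to the lower strand index; maxNN(j) profiles the furthest
separation per position. Dissolution is decided per glycan on NN(s,j) —
the per-glycan decision is what feeds a dissolved *mass* — while maxNN is
emitted for separation profiles.

Threshold calibration pools maxNN(j) over all glycan indices (strand ends
included) at the listed control timepoints, using the population standard
deviation, and sets mean + k·σ with k = 4. On the published control
moments (mean 6.51 Å, σ 0.16 Å) this gives 7.15 Å, within rounding (0.01 Å)
of the 7.16 Å obtained from unrounded statistics. The threshold comparison
is strictly `>`: a glycan exactly at threshold is intact. wt % uses the
162.14 amu anhydroglucose mass against solvent masses summed per species
from the topology; rates are ordinary least squares via
`scipy.stats.linregress`.

One known property of the NN statistic, inherited from its definition: if
a strand's *only* near neighbor departs, the abandoned strand's NN jumps
to the next-nearest strand and can cross the threshold without that strand
moving. The default layouts avoid this (every strand keeps a 3.9 Å stack
neighbor), and the injection test scores false positives only on untouched
strands, with a ±1 Å band around the threshold excluded from scoring since
0.3 Å atomic jitter moves the COM statistic by ~0.1 Å.

## Energies

E(r) = 4ε[(σ/r)¹² − (σ/r)⁶] + 332.0636·q₁q₂/r with Lorentz–Berthelot
mixing, plain truncation at 20 Å (no switching, shifting, or tail
corrections) and no mesh Ewald: the decomposition compares groups within
one convention, and its acceptance is via closed forms (−332.0636 kcal/mol
for ±1 e at 1 Å; LJ zero at r = σ, depth −ε at 2^{1/6}σ) and exact
agreement with all-pairs oracles, not absolute energetics. Exclusions are
bonded paths of length ≤ 3 (1–2, 1–3, 1–4) by breadth-first search; the
peeling strand's self term retains 1–5-and-further pairs. Per-species
solvent terms are the full pair sum between that species' atoms and the
strand (no per-molecule proration at the cutoff boundary).
`pair_energy(A, B)` canonicalizes group order internally so the Newton
symmetry E(A,B) = E(B,A) holds exactly, not just to round-off. Parameters
come from a plain-text `name charge epsilon sigma` file; a built-in toy
table (neutral glycans and waters, +1 TBP, −1 Cl) serves the synthetic
demos.

## Twist and presentation smoothing

The junction torsion is the signed O5-C1-O4-C4 dihedral (O5, C1 from
glycan j; O4, C4 from glycan j+1), IUPAC sign convention, range
(−180°, 180°], reported at glycan number j + 0.5. Time traces are smoothed
with a centered rolling mean and decimated (1000-point window, every 100th
point at production scale; the demo scales this to its short runs).
Centered windows truncate at the series edges so traces start at t = 0;
trailing windows are a config switch away.

## Demo scale and determinism

The shipped demo builds the 18×12 bundle (4 590 cellulose atoms) with a
65:111 TBPCl:water box — the 63.1 mol %-water ratio at a size that keeps
the full build → solvate → peel → analyze cycle near half a minute — and
runs 60 frames at 10 ps spacing. Because the kinematic peel cannot push
solvent aside, the demo deletes solvent molecules from the corridor the
planted strand sweeps; otherwise overlap spikes the LJ term. All
randomness flows from explicit seeds; identical seeds give byte-identical
outputs, which both the test suite and the acceptance script assert.

## Known limitations

- The bundle geometry reproduces the hydrogen-bond *network*, not Iβ
  crystallographic coordinates; absolute energies on built geometry are
  not physical.
- Gaussian jitter has no temporal correlation; lifetime estimates on
  jittered coordinate data (as opposed to telegraph series) reflect the
  jitter model, not solvent kinetics.
- Truncated Coulomb at 20 Å omits long-range electrostatics; group
  *comparisons* are meaningful, absolute sums are convention-dependent.
- A bundle-level "% twisting" summary is not defined here — only
  per-junction torsion profiles; defining a bundle scalar would require an
  external experimental convention.
- Triclinic boxes, velocities/forces, and binary trajectory formats (DCD)
  are out of scope.
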