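# Methods

`pathpmf` computes minimum free-energy paths (MFEPs) and potentials of mean
force (PMFs) for reactions described by a small set of collective variables
(CVs), with the two-step serine-hydrolase acylation — nucleophilic attack
through a shallow tetrahedral intermediate (TI), coupled to an aromatic
ring-orientation change — as the motivating system.  This note records the
models, the numerical choices, and what the synthetic benchmarks do and do
not demonstrate.

## Geometric CVs

Four CV kinds operate on plain coordinate frames (PDB via biotite, XYZ via a
small built-in reader): interatomic distance, torsion angle, signed
point-to-plane distance, and the acute angle between two ring planes.

* **Best-fit planes** use total least squares: the normal is the smallest-
  variance principal axis of the centered ring coordinates, which is
  independent of atom ordering; the sign of signed distances is fixed by the
  cross product of the first three (ordered) atoms.
* **Torsions** use the standard right-handed atan2 convention (cis = 0°,
  trans = 180°, mirror image flips the sign) and are reported in (−180°,
  180°].
* **Gradients** are analytic for distances and torsions and high-accuracy
  central differences (step 1e-5 Å) for the two plane-based CVs — the
  derivative of a smallest-eigenvector plane fit buys nothing over finite
  differences at the accuracy the biasing forces need.  All gradients are
  validated against central differences and satisfy translational
  invariance (zero net force).
* Units are Å and degrees at every interface; radians appear only inside
  formulas.

The T-stacked ⇄ parallel ring-flip geometry is exercised on constructed
(synthetic) ideal ring pairs in `pathpmf.fixtures`: two regular hexagons
stacked 3.5 Å apart.  The four atoms defining the surrogate dihedral θ are
chosen so that two of them sit on the ring's rotation axis; θ then equals
the ring rotation angle exactly (θ = 0° at the T-stack, where the plane
angle is 90°; θ = 90° at the parallel stack, plane angle 0°).  Which four
atoms define θ in a real complex is a modelling decision left to the user's
CV configuration; nothing is hard-coded.

## Synthetic energy surfaces

The sampling machinery is validated on analytic surfaces, not on quantum-
chemical data; the surfaces are designed to reproduce the *structure* of
the acylation problem.

**Two-step surface.** Coordinates (r, θ): a reaction coordinate r and a
periodic angle θ (degrees).  The backbone V(r) is a C² quintic Hermite
through five knots — reactant (MC, 0), first barrier (TS1, 14), shallow
intermediate (TI, 13), second barrier (TS2, 16), product (AE, −2), in
reduced units chosen so that numbers read as kcal/mol at 300 K
(kT = 0.5962) — with zero slope at each knot, knot curvatures from local
second differences (backed off automatically, down to the monotone
zero-curvature quintic, if a parameter set would otherwise create spurious
extrema between knots), and harmonic confinement walls outside [r_MC,
r_AE].  A C¹-only backbone was rejected: a curvature jump located exactly
at a barrier top breaks any estimator that Gaussian-approximates windows
sampling across it.  The default TI depth is 1.0 — the "shallow or absent"
regime.  These defaults are the package's chosen study conditions, not
values taken from any particular enzyme.

θ is tied to a reaction-dependent equilibrium θ_eq(r), a logistic switch
from ≈0° (T-stacking) to ≈90° (parallel) of width 0.18 centered mid-
reaction, through a harmonic coupling κ·wrap(θ − θ_eq(r))² with κ = 0.006
energy/deg² (thermal θ spread ≈ 7°).  Because κ is constant, the exact
marginal free energy over θ equals V(r) up to a constant — which is what
makes the quadrature oracle sharp.  `theta_friction` scales the Langevin
friction on θ and is the dial for the slow-ring-relaxation ablation.

**Müller–Brown** is included unmodified as the standard MFEP validation
surface.

**Oracles.** `exact_marginal_pmf` integrates the off-coordinate by
trapezoid quadrature with grid doubling until successive profiles agree to
1e-4.  `reference_mfep` locates stationary points by polishing gradient
roots seeded from a dense grid, classifies them with finite-difference
Hessians, and concatenates normalized steepest-descent paths from each
saddle (descent step 2e-3, with automatic step backoff once progress
stalls so basin-bottom jitter cannot inflate the path's arc length — an
inflated arc was found to corrupt downstream arc-length comparisons).

## Sampling

BAOAB Langevin splitting with unit masses per *scaled* coordinate: each CV
is divided by its metric scale (1 per distance-like unit, 30° per angular
unit by default), and masses are set to 1/scale² so every scaled coordinate
relaxes on the same timescale.  The timestep defaults to 1/50 of the period
of the stiffest mode among bias springs and local surface curvature;
friction defaults to critical damping of the bias mode, which minimizes the
correlation time of window means.  All bias energies use the MD-engine
convention E = k·(x − x₀)² (no ½), switchable to the ½ convention.  The
one-sided flat-bottom restraint is zero below its onset, harmonic up to the
linearization point, and continues linearly with matched value and slope
(C1 at both switch points).

Walkers run as one vectorized ensemble (all string nodes or umbrella
windows at once) driven by a single seeded generator per stage, so a fixed
seed reproduces every trajectory bit for bit.

## Adaptive string method

A 96-node string (the default discretization) evolves by mean drift: each
node samples under a harmonic tether, moves a fraction η toward its sampled
mean CV (circular means for periodic CVs), the endpoints are re-anchored by
local minimization started from the node (never from the diffused walker,
which would random-walk endpoints along flat directions), and the string is
reparameterized to equal arc length.  Tether constants are auto-tuned to
k = 2·kT/h² in scaled space (stationary spread of half a node spacing h).
The mean-drift fixed point is the MFEP; no explicit mean-force projection
is needed.

Two practical findings shaped the defaults:

* **Reparameterize every few iterations (default 2), not every one.**
  Resampling on chords is a weak curve-shortening flow; at tight bends its
  inward pull balances the restoring drift at a standoff distance
  independent of node count.  Spacing the resampling lets drift win.
* The string returned to callers is always equidistant (a final
  reparameterization), because its nodes double as umbrella-window centers.

On Müller–Brown the converged string agrees with the steepest-descent
reference to a Fréchet distance of ≈0.03 (tolerance 0.05), about one node
spacing.

## Path-CV umbrella sampling and umbrella integration

The progress coordinate s is the normalized arc length of the closest point
on the (scaled, periodic-aware) path polyline; z is the perpendicular
distance.  Projection ties resolve toward smaller s.  Windows are centered
at equally spaced s (by default two per node interval — denser centers cost
almost nothing in the vectorized ensemble), with k_s = 2·kT/h² and a
harmonic tube restraint k_z = k_s/L² on z, as stiff transversally as the
windows are longitudinally.  The tube is not optional on this landscape:
near a saddle the direction perpendicular to the path has negative
curvature and unrestrained windows slide into the flanking basins.

Two geometric failure modes of polyline path-CVs were identified and are
engineered away:

* **Vertex wedges.**  At a polyline vertex, s is locally constant over a
  wedge-shaped region; a window centered there accumulates a point mass at
  one s value and its Gaussian summary is wrong.  The string is therefore
  spline-resampled to ~1000 points before umbrella sampling, making every
  kink negligible, and the s-force at a vertex projection keeps the
  adjacent segment's tangent instead of being zeroed (on the dense curve
  the wedge is a discretization artifact; dropping the force measurably
  tilts the whole PMF).
* **Medial-axis crossings.**  Where the path bends with radius smaller than
  the tube width, walkers can cross the set where the projection jumps
  between path branches; s is discontinuous there but carries no opposing
  force, so sampling silently smears.  The pre-umbrella resampling
  increases the spline smoothing until every bend radius exceeds four tube
  standard deviations.

Umbrella integration follows the standard per-window Gaussian construction:
dA/ds|ᵢ = kT(s − s̄ᵢ)/σᵢ² − dUᵢ/ds, mixed with weights ∝ nᵢ·N(s; s̄ᵢ, σᵢ²)
and integrated by trapezoid; it is exact for quadratic A with Gaussian
windows (machine precision on exact moments).  Windows whose means separate
by more than three combined standard deviations raise a coverage error.

95% confidence bands come from a moving-block bootstrap (block length =
integrated autocorrelation time estimate, capped at n/10; ≥50 replicates),
re-normalized at the reactant minimum of the point estimate; the halfwidth
is 1.96 × the replicate standard deviation.  The workflow-level convergence
rule doubles every window's sampling until the CI at the highest interior
barrier falls below 1.0 reduced kcal/mol.

**What A(s) is.**  With the tube restraint, A(s) is the free energy along
the path *within the tube*.  On the default surface its stationary values
track the exact marginal F(r) to a few tenths of a unit; the residual
(tube-entropy and path-curvature terms) is a known, documented limitation —
no Jacobian or curvature corrections are applied.

## Stationary points and classification

Profiles are min-normalized; extrema come from discrete slope changes, then
adjacent extremum pairs are pruned smallest-first while their amplitude is
below a local depth threshold — by default max(local CI, 0.1), so an
intermediate shallower than its own uncertainty is not called.  A profile
is *two-step* iff a qualifying interior minimum survives between two
maxima.  Pipeline reports additionally ignore extrema within 3% of the
profile ends, where the UI integration has small boundary wiggles.

## Spline correction to a higher-level energy function

`build_correction` evaluates a low-level and a high-level surface at
equally spaced points along the path (optionally relaxed on the low-level
surface within the tube cross-section, bounded to a 0.2 scaled-unit radius
so the relaxation stays local); `spline_correct` interpolates
ΔE = E_high − E_low with a cubic spline and adds it to the PMF
(`add_high_minus_low`; the opposite sign is selectable), then re-analyzes
stationary points.  The default boundary condition is not-a-knot, which
reproduces polynomial ΔE up to cubics exactly; natural and clamped are
accepted.  Confidence bands are propagated unchanged — single-point
energies carry no sampling error of their own.  `check_path_similarity`
quantifies the method's core assumption (similar low- and high-level paths)
as an arc-length-matched RMSD and warns, rather than fails, beyond
tolerance.

## Problem sizes

Defaults used by the test suite and the analysis scripts: 96 string nodes
(48 for reduced runs), 250 sampling steps per node per string iteration,
≤150 string iterations, 191 umbrella windows × 4000 steps per convergence
round (doubling per round, typically ≤3 rounds), 100–200 bootstrap
replicates, and 10 seeds per arm of the ablation study.  These sizes make
every benchmark reproducible on a single CPU in minutes while keeping the
statistical errors well below the effects being measured.

## What the synthetic benchmarks show — and what they do not

Passing tests demonstrate that the pipeline's numerics are correct on
landscapes with the right structure: two sharp barriers around a shallow
minimum, a coupled slow orientation coordinate, realistic barrier-to-kT
ratios.  They do not demonstrate anything about real enzymes: the surfaces
are two-dimensional, the coupling is harmonic with constant stiffness,
sampling is Langevin dynamics on the CV space rather than molecular
dynamics in Cartesian space, and there is no solvent, no protein
fluctuation spectrum, and no quantum-chemical energy anywhere.  The
geometric CV layer is exact, so its tests transfer directly; everything
else transfers as *algorithm* validation only.

## Known limitations

* A(s) is a tube free energy; curvature/Jacobian corrections are not
  applied.
* The UI confidence band treats windows as independent (they are, by
  construction of the ensemble) but propagates no error from the string's
  own position.
* The correction stage assumes low- and high-level paths coincide; the
  similarity check warns but cannot repair a genuinely different
  high-level mechanism.
* Center-of-mass-style CVs are supported only as equal-weight point
  combinations.
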