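# Methods

This note documents the models, numerical choices and deliberate
approximations behind `aptamd`, in the order the pipeline uses them.

## Scope and units

The package analyses trajectories of an RNA aptamer–ligand complex; it
does not run molecular dynamics itself.  All lengths are in Å, energies in
kcal/mol, times in ps, charges in elementary units; residue indices follow
the 1-based author numbering of the source structures (G5, C15, …)
everywhere in the interface.  Structures and trajectories travel as
multi-model PDB (fixed columns; first alternate location kept, insertion
codes rejected), per-atom parameters as TSV keyed by (residue name, atom
name), 3D densities as OpenDX, everything else as TSV.

## Base stacking (rectangle projection)

A least-squares plane (smallest singular vector of the centred ring
coordinates) is fitted to the ligand ring atoms.  The projected ring atoms
are framed by their in-plane principal axes, and the rectangle is their
bounding box expanded by a margin (default 0.5 Å) on every side.  A base
is "in" when its ring-atom geometric centre projects inside the rectangle;
the vertical distance is the unsigned distance of that centre from the
ligand plane.  Choices worth noting:

* the rectangle is re-oriented per frame from the principal axes, making
  the construct invariant under rigid motions (verified by property test);
* a projection exactly on the edge counts as "in" — a measure-zero tie,
  fixed for determinism;
* the nucleobase "centre" is the geometric centre of the selected ring
  heavy atoms.

The classification is cross-checked against an explicit corner-based
point-in-polygon test on 10⁴ random rigid configurations.

## Hydrogen bonds

d(donor, acceptor) < 3.5 Å AND angle(donor–H–acceptor) > 120°, strict
inequalities, angle measured at the hydrogen.  A definition may list
alternative acceptors (an OR-group, e.g. "O6 / N7"); the group counts as
one bond if any alternative qualifies.  Occupancy is the fraction of
frames in which the bond is present; occupancies are monotone
non-increasing under stricter cutoffs (property test).

## Pocket frame and collective variables

The pocket centre is the geometric centre of the heavy atoms of the six
pocket-lining residues (G5, U6, G11, C15, C16, C30).  The bisecting plane
passes through three named atoms (U6 C1', A10 C1', C15 C4); its normal is
oriented so the midpoint of the G5/G11 C1' front markers has z > 0.  Per
frame, r is the distance from the ligand heavy-atom centre to the pocket
centre and z its signed coordinate along the normal; the frame is
recomputed every frame, so the analysis lives in the moving frame of the
RNA.  Θ between two groups of bases is the mean acute angle between their
fitted plane normals over all cross-group pairs (range 0–90°).

Grid densities count selected-atom positions in cubic voxels (default
0.5 Å; auto-sized to the bounding box + 3 Å unless specified); particles
off-grid go to an overflow tally so mass is conserved exactly.  Optional
Gaussian smoothing conserves mass to 1e-9.  Site occupancy is the fraction
of frames with any selected atom within 2 Å of the site; density peaks are
26-neighbour local maxima above 0.5 of the global maximum (both
configurable).

## Unbinding/rebinding events

A two-state machine over the (r, z) trace: starting bound (IN), the first
frame with r ≥ 9 Å emits *unbind* (→ OUT); in OUT the first frame with
r ≤ 1 Å emits *rebind* (→ IN).  Crossings are inclusive (≥/≤) at the first
qualifying frame.  Because biased simulations expel the ligand almost
immediately, the first unbind is discarded by default and counting starts
at the subsequent rebind, so per trajectory events strictly alternate
beginning with a rebind.  The door is front if z > 0 at the event frame,
back if z < 0; z = 0 classifies as front (measure-zero tie).  No smoothing
and no dwell-time requirement are applied to r(t).

## MM-PBSA

Single-trajectory protocol: receptor and ligand coordinates are taken
from the complex snapshots, so intramolecular terms cancel and
ΔE_ele/ΔE_vdW reduce to the intermolecular sums.

* **Coulomb**: k_C Σ q_i q_j / r_ij over all cross pairs, no cutoff, with
  k_C = 332.0636 kcal·Å/(mol·e²) (the AMBER-convention value, exposed in
  the config).
* **Lennard-Jones**: ε_ij[(R_ij/r)¹² − 2(R_ij/r)⁶] in Rmin/ε form with
  Lorentz–Berthelot combination, matching the force-field ecosystem the
  parameters come from.
* **Polar solvation**: finite-difference linear PB at zero salt (i.e.
  Poisson) on a cubic grid, default 0.4 Å spacing.  Charges are spread
  trilinearly; the dielectric boundary is the molecular (solvent-excluded)
  surface built on-grid from a 1.4 Å probe: solvent-accessible probe
  centres are found from the exact atom-sphere distance field, a Euclidean
  distance transform dilates them by the probe radius, and a sub-grid
  correction (subtracting the nearest accessible node's overshoot beyond
  the true accessible boundary) makes the signed surface distance exact for
  isolated spheres and suppresses grid-placement sensitivity.  Face
  dielectrics are harmonically interpolated where the surface cuts a grid
  edge.  Dirichlet boundaries carry the solvent-screened Coulomb potential
  of all charges.  Red-black SOR (ω = 1.9) relaxes the 7-point stencil for
  a fixed sweep count (default 5000); the residual is logged every 100
  sweeps, and an optional residual tolerance (default 1e-8) stops early
  once converged — the fixed count is the fallback, the tolerance only
  truncates sweeps that no longer change the answer.  The reaction-field
  energy is ½ Σ q_i (φ_solvated − φ_homogeneous) interpolated at the atom
  positions, with the homogeneous reference solved on the same grid so the
  grid self-energy cancels.  Accuracy: the Born ion (q = 1 e, R = 2 Å)
  is reproduced to ~1% at 0.4 Å spacing with the corrected surface;
  with the plain (uncorrected) surface the error is larger and decreases
  monotonically under dyadic refinement 0.8 → 0.4 → 0.2 Å, which is the
  textbook O(h) convergence the refinement check exercises.  Auto grids pad
  by max(30% of the molecular extent, 6 Å), configurable.
* **Nonpolar solvation**: γ·SASA + β with γ = 0.00542 kcal/mol·Å² and
  β = 0.92 kcal/mol.  SASA is Shrake–Rupley with a deterministic golden-
  spiral point set (default 960 points per atom) on probe-inflated
  spheres; an isolated sphere matches 4π(r+p)² to ≤ 0.5%, two-sphere
  overlaps match the spherical-cap closed form to ≤ 1%.
* **Entropy**: operates on supplied normal-mode frequencies (Hessian
  construction is out of scope).  Vibrational entropy per mode is the
  quantum-harmonic-oscillator expression
  S/R = x/(eˣ−1) − ln(1−e⁻ˣ), x = hcν̃/kT, verified against the numeric
  derivative of the QHO free energy; translations use Sackur–Tetrode at
  1 atm and rotations the classical rigid rotor with σ = 1 by default.
* **Statistics**: components are averaged per replicate over frames, then
  mean ± SEM (SD/√n) across replicates; ΔH and ΔG_bind are assembled from
  the five terms and the identities ΔH = ΣE-terms and ΔG = ΔH − TΔS hold
  to 1e-9 by construction.
* **Per-nucleotide decomposition** (enthalpic terms only): ΔE_ele and
  ΔE_vdW are assigned pairwise-exactly (each RNA residue receives its pair
  sums with the ligand, so shares sum to the totals); ΔG_nonpol uses
  per-atom SASA differences scaled by γ, with ligand-atom terms and the −β
  offset carried in the ligand row so the column still sums to the total;
  ΔG_pol uses charge annihilation (zero one residue's charges, re-solve,
  difference) — a well-defined but approximate scheme, since the PB
  response is not strictly additive.
* ΔG_exp = RT ln K_D with R = 1.9872×10⁻³ kcal/(mol·K) at 300 K — the
  temperature that reproduces the printed experimental values, adopted as
  the default.

## Synthetic data generator

The toy pocket is a rigid geometric stand-in, not an energy-minimised
structure: a planar ligand ring at the origin (ring radius 1.4 Å), a
"G11" plate ring at +plate_gap/2 above it and "G5"/"C16" plates below
(default plate_gap 3.4 Å, so the rectangle metric sees vertical distances
of 1.7 Å), in-plane pseudo-bases "U6", "C15", "A29" offering donor/
acceptor partners at 2.9 Å, and C1' marker atoms spanning the front
(G5–G11, default 12 Å, the bound-state width) and back (C15–C30, default
7.8 Å, the apo/cognate width) doors.  The bisecting-plane markers are
placed on the plane through the pocket centre so the (r, z) frame is exact
and 2D toy trajectories embed and re-measure losslessly.  Because the
plates sit closer than Lennard-Jones contact, energetic demonstrations use
a contact-distance pose (plate_gap 7 Å); the geometry defaults serve the
geometric analyzers.

Programmed trajectories switch discrete states through two-state Markov
chains rather than i.i.d. draws, so frame-to-frame autocorrelation exists
as in real MD: with stationary occupancy p and switch parameter s, the
per-frame transition probabilities are s(1−p) out of and s·p into the
occupied state (autocorrelation decay 1−s per frame; default s = 0.8).
"Off" states displace the relevant atoms far past the classification
cutoffs (plates shifted 5 Å laterally; H-bond partners moved 1.6 Å outward,
2.9 → 4.5 Å; the C15-like base rotated 90° about its radial axis), and all
atoms receive Gaussian noise (default sd 0.15 Å) small enough that the
analyzers recover the ground-truth log essentially exactly.  Ion
trajectories place each ion per frame at a named site (noise sd 0.3 Å) or
uniformly in a bulk box, i.i.d. with the programmed probabilities.

What the generator does *not* emulate: real force-field energetics,
solvent, correlated collective motions, drift, or conformational substates
beyond the programmed two-state switches.  Passing the recovery suite
therefore shows the analyzers are correct and unbiased at realistic
occupancies and noise levels — not that they are robust to every artefact
of real trajectories.

## Well-tempered metadynamics toy

A 2D overdamped Langevin particle (Euler–Maruyama; D = 0.25 Å²/ps,
dt = 0.02 ps, so the random step sd of 0.1 Å is one fifth of the hill
width) moves in a designed landscape: a Gaussian bound well at the origin
(depth 6 kcal/mol) and, beyond a smooth gate at r ≈ 3 Å, an angular
profile with two Gaussian channels around +z (front, floor 3 kcal/mol) and
−z (back, floor 5 kcal/mol) separated by 12 kcal/mol side walls, plus a
soft harmonic wall beyond 12 Å mirroring the restraint that keeps a ligand
near the RNA.  The persistent side walls confine an escaping particle to
the channel it chose, so the sign of z faithfully records the door — with
a 2 kcal/mol asymmetry the front:back escape ratio is large
(≈ exp(ΔΔU/kT) ≈ 28 under intra-well angular equilibration) and ensembles
comfortably exceed the 70% front fraction the event suite checks.

Bias acts on the collective variable r (distance from the origin),
tabulated on a grid of spacing width/5 with linear interpolation.  Every
deposit interval (default 500 steps, a toy choice — the interval is not
fixed by the emulated protocol) a Gaussian hill of width 0.5 Å is added
with the well-tempered height h₀·exp(−V_bias/((γ−1)kT)), h₀ = 1.2
kcal/mol, γ = 15.  The free-energy estimate is −γ/(γ−1)·V_bias; to damp
the residual hill ripple the estimator averages the bias over the second
half of the deposits (a standard time-averaged estimator).  On a 1D double
well (wells ±2 Å, 3 kcal/mol barrier) the reconstruction RMS is ~0.3
kcal/mol over the sampled range after 400k steps; the integrator itself is
cross-checked by Boltzmann-histogramming a long unbiased run at a reduced
barrier.  A step larger than 5 hill widths aborts with an integration
error advising a smaller timestep.

## Problem sizes

Defaults used by the test suite and the acceptance script: occupancy
recovery at 5000 frames (99% binomial intervals); the stacking oracle at
10⁴ random configurations; Coulomb/LJ oracles at 100 random instances;
door statistics from ensembles of 300k-step metadynamics runs until ≥ 50
unbinding events; PMF reconstruction from one 400k-step 1D run; the PB
refinement series on 0.8/0.4/0.2 Å grids with 4 Å padding.  These sizes
were chosen as the smallest at which the statistical checks have
comfortable margins.

## Known limitations

* The PB solver is linear and zero-salt only; no nonlinear PB, no ionic
  strength, no Generalized Born alternative.
* The on-grid molecular surface approximates probe rolling by distance
  transforms; deep reentrant features are resolved only to grid precision.
* The charge-annihilation ΔG_pol decomposition is one of several defensible
  schemes and will not match other software's decompositions exactly.
* The toy pocket validates analyzers, not physics: its occupancies, door
  statistics and energies are designed conditions, not predictions for any
  real aptamer.
* Binary trajectory formats (DCD/XTC) and mmCIF are not supported; inputs
  are multi-model PDB at toy scale.
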