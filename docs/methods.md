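# Methods

`sh2dock` models the computational workflow used to study peptidomimetic
inhibitors of the STAT3 SH2 domain: anchor-constrained incremental docking
of large phosphotyrosine-mimetic ligands, post-MD trajectory analytics
(pose-stability RMSF, conformational clustering, hydrogen-bond occupancy),
end-point MM-GB(SA)-style affinity estimation with a harmonic entropy
term, conversion of competition-assay IC50 values to binding free
energies, and classification of bound conformations into the bent,
extended and wedged binding modes of the SH2 ligand groove.  Everything is
exercisable on synthetic toy systems; no external structures or downloads
are required.

## Energy surrogate

Docking engines ship calibrated empirical scoring functions; this package
deliberately does not reproduce one.  All energetics run through a
self-contained surrogate:

* **Lennard-Jones** with geometric (OPLS-style) mixing,
  ε_ij = √(ε_i ε_j), σ_ij³ = σ_i^{3/2} σ_j^{3/2}.  Geometric mixing makes
  the receptor field exactly separable into three probe-independent grid
  maps (r⁻¹² kernel, r⁻⁶ kernel, electrostatic potential), so the grid
  path equals the direct sum up to interpolation error.
* **Coulomb electrostatics** with distance-dependent dielectric
  ε(r) = 4r and the constant 332.06 kcal·Å/(mol·e²).
* **Polar solvation** by a Hawkins–Cramer–Truhlar pairwise-descreening
  generalized Born model with the Still pair function
  f = √(r² + α_i α_j e^{−r²/4α_iα_j}).  Born radii use the vdW radii
  directly (no Amber-style 0.09 Å offset), which keeps the single-ion
  Born limit exact — convenient for verification and adequate for a
  surrogate.
* **Nonpolar solvation** as γ·SASA + b (γ = 0.00542 kcal/mol/Å²,
  b = 0.92 kcal/mol) with Shrake–Rupley sampling on a deterministic
  golden-spiral point set (default 240 points/atom).  In the binding
  decomposition ΔG_nonpolar = γ·ΔSASA: the offset b is an absolute-scale
  reference and cancels by convention.

Numerical guards: the per-pair LJ repulsion is capped at 10⁵ kcal/mol
(configurable); because a capped r⁻¹² wall would otherwise be overwhelmed
by the uncapped r⁻⁶ and 1/r² attractions as r → 0, both the LJ and
Coulomb terms evaluate distances through a 1 Å floor.  Inside that range
the surrogate is not physical — it only needs to be strongly repulsive
and bounded.

Grid maps use trilinear interpolation (default spacing 0.375 Å).
Interpolating a near-singular r⁻¹² kernel is accurate only outside the
repulsive wall; grid/direct agreement is therefore quoted for poses that
do not interpenetrate the receptor, and the energy code falls back to the
direct path (with a warning) when a ligand atom leaves the box.

## Incremental docking

The ligand is decomposed into a torsion tree: rigid units are the
connected components left after cutting rotatable bonds, ring bonds
(graph non-bridges) are forced rigid, and bonds that would rotate only a
single terminal atom are demoted.  The root unit contains the phosphorus
anchor.  Docking proceeds dock–select–grow–dock: the rigid root is placed
first (seeded at the phosphate sub-pocket in random orientations), then
torsions activate in breadth-first tree order, three per increment by
default.  Selection uses the anchor-penalized score

    S = w · ‖x_P − x₀‖² + E,

with w = 1 (kcal/mol)/Å² by default; x₀ defaults to the centroid of the
phosphate sub-pocket residues.  Setting w = 0 recovers unconstrained
energy-only docking.

Partial poses are scored on the grown fragment only — atoms that belong
to not-yet-activated subtrees are excluded from every energy term.  This
matters: scoring the full ligand at reference internal geometry steers
the root placement toward orientations that accommodate an un-grown tail
and systematically misses the true pose.

The inner search per increment is seeded simulated annealing (geometric
cooling, default 5 → 0.2 in 600 steps, 3 restarts per seed): each
proposal is either a Gaussian rigid-body move or a Gaussian step on one
newly activated torsion; previously placed torsions stay frozen.  Two
refinements make the protocol reliable on narrow binding grooves:

1. **Greedy rotamer initialization** — each newly activated torsion is
   first set by a 24-point coarse scan (holding everything else fixed)
   before annealing, so grown segments start inside the groove instead of
   inside its walls.
2. **Final polish** — once all torsions are active, each retained pose is
   relaxed by one low-temperature annealing pass with *all* degrees of
   freedom live, settling it into its local optimum.  (During growth the
   frozen-prefix rule is strict.)

Defaults keep the 16 best partial poses per increment.  A smaller beam
(≈10) is noticeably less robust on 10-torsion ligands: the partial-pose
ranking can be dominated by one over-optimized dead-end family, and a
slightly wider beam preserves extendable alternatives at modest cost.
Every increment is recorded in an audit log (kept scores and anchor
distances).  A fixed seed makes the whole protocol bit-reproducible.

## Trajectory analytics

Preprocessing strips water/counterions, centers each frame and superposes
it onto frame 1 by mass-weighted Kabsch fitting (proper rotations only;
`scipy`'s weighted `align_vectors` underneath).  Defaults fit on all
atoms of the complex; the weight vector is configurable.

* **RMSF (pose stability)** follows the frame-averaged definition: the
  mean over frames 2..N of the mass-weighted RMSD of the ligand to its
  conformation in frame 1.  This is *not* the conventional per-atom
  fluctuation, which is provided separately as `rmsf_per_atom` to avoid
  ambiguity.
* **Clustering** is k-means (k = 5 by default) with RMSD as the metric:
  on a fitted ensemble the mass-weighted RMSD is a Euclidean distance on
  √w-scaled flattened coordinates, so standard k-means applies
  (`sklearn` with deterministic farthest-point seeding from a seeded
  RNG).  Cluster representatives are medoids — reproducible and anchored
  to actual frames.  Degenerate solutions (fewer distinct clusters than
  k) are flagged.
* **Hydrogen bonds** use geometric criteria — donor–acceptor distance
  ≤ 3.5 Å and donor–H···acceptor angle ≥ 120°, both configurable — in
  both directions between ligand and receptor.  Donor hydrogens are
  paired with their nearest heavy atom (within 2 Å, tolerant of thermal
  jitter).  Per-residue occupancy is the fraction of frames in which the
  residue takes part in at least one bond (union over its bonds);
  residues below 50% occupancy are flagged as dropped.

## Affinity estimation

ΔG_bind = ⟨ΔE_MM + ΔG_polar + ΔG_nonpolar⟩ − TΔS with the single-
trajectory decomposition (complex, receptor and ligand from the same
frames, so intramolecular MM terms cancel and ΔE_MM is the inter-species
term).  Four schemes: A (GB, no entropy), B (externally supplied PB
energies, no entropy), C = A − TΔS, D = B − TΔS.  A Poisson–Boltzmann
solver is out of proportion for this package: the PB channel is an input
CSV of per-snapshot Δ-components, never computed natively.  Averages can
be restricted to a leading prefix of frames (default grid 0.2…1.0) to
emulate estimates from truncated simulations; on stationary input the
estimates converge to the generative mean as the prefix grows.

The entropy term comes from harmonic normal-mode analysis: a central-
difference mass-weighted Hessian of any energy callable, the 6 smallest-
magnitude modes removed (5 for linear species, with a warning if more
modes are near zero), and the quantum harmonic-oscillator entropy at
298 K.  An optional plain gradient-descent pre-relaxation is available
for structures that are not yet stationary points.  Default stride for
entropy snapshots: every 100th frame.

Experimental IC50 values convert via Cheng–Prusoff,
Ki = IC50 / (1 + [probe]/K_d) with the assay constants 10 nM probe
concentration and 150 nM probe K_d, then
ΔG_exp = RT ln(Ki in mol/L) with R = 0.001986 kcal/(K·mol), T = 298 K
(a log10 variant is exposed for sensitivity analyses).  Censored IC50s
(reported only as a bound) enter correlations at the bound and are
flagged; an option excludes them.  Pearson correlations between
estimated and experimental ΔG are computed per prefix fraction.

## Binding-mode classification

Sub-pockets follow the SH2-domain residue sets: sub-pocket-1 (Lys591,
Arg609, Ser611, Glu612, Ser613 — the phosphate pocket), sub-pocket-2
(Glu638, Tyr640, Gln644), sub-pocket-3 (Gly656, Tyr657, Lys658),
sub-pocket-4 (Trp623, Ile659, Met660), plus the groove loops 623–629 and
656–668.  A moiety contacts a sub-pocket when any heavy-atom pair is
within 4.5 Å (configurable; the CLI reports a 4.0–5.5 Å sensitivity
sweep).  With the anchor in sub-pocket-1, the C-terminal moiety decides
the label: sub-pocket-2 → bent, sub-pocket-3 → extended, both loops
engaged with neither named sub-pocket dominant → wedged.  No quantitative
bent/extended/wedged boundary exists for intermediate poses, so
precedence is a declared convention (wedged > extended > bent by contact
count; exact cross-precedence ties are reported as unclassified with the
candidates listed).  The C-terminal moiety is a user-designated atom set;
chemical perception is out of scope.

## Synthetic data: what it emulates, and what it does not

The generators plant known answers so that every analysis stage can be
verified against ground truth.

**Toy system.** The ligand is a flexible chain (anchor phosphorus with
charge −1.5 e at one end, alternating ±0.25 e partial charges with
alternating 1.45/1.85 Å radii, two acceptor oxygens, one donor hydrogen,
a designated C-terminal moiety; 0–30 rotatable bonds).  The pocket is
built around a planted conformation of that chain: a ring of five
positive pseudo-atoms (+0.7 e) around the anchor plays the phosphate
sub-pocket, and a dense tube of pseudo-atom rings along the planted chain
path forms the binding groove — a conformation threading the tube is
buried on all sides, anything draped outside touches far fewer wall
atoms, the anchored phosphate fixes the registration along the path, and
an end-cap ring closes the tube beyond the C-terminal atom so the tail
cannot slide out.  The tube walls sit 0.35 Å beyond LJ contact: enough
slack that near-planted threads remain extendable during incremental
growth, tight enough that the planted thread is the well bottom.
Pseudo-residues reuse the SH2 numbering (591…668) so the default
sub-pocket configuration works unchanged.  Wall and sub-pocket
pseudo-atoms are given 100 amu masses: the pocket is an idealized rigid
scaffold, and the heavy masses anchor the mass-weighted superposition on
it.  Keying and refinement are iterated to self-consistency — the pocket
is rebuilt around the refined pose until the pose stops drifting —
because walls keyed to a pre-refinement conformation would leave the
planted pose off the tube centerline and make a recentered thread, not
the planted pose, the energy optimum.  The final pose is verified to be
a strict local optimum and lower-energy than 100 random poses;
generation retries with a derived sub-seed when a sampled conformation
self-clashes or fails verification.

**Planted trajectory.** Frames are Gaussian jitter (default σ = 0.15 Å
per coordinate) around per-cluster reference conformations — the planted
ligand pose translated by well-separated offsets — with exact per-cluster
frame counts (largest-remainder allocation) and light jitter on the
receptor (σ = 0.03 Å).  Scripted hydrogen bonds toggle a dedicated
receptor O–H donor pair between an in-criteria geometry (3.2 Å, 180°)
and a 6 Å separation; the scripted donor and acceptor atoms are placed
exactly (no jitter), and present-frame counts are realized exactly
(half-up rounding), so scripted occupancies are recovered to machine
precision.  The scripted donor oxygens are not flagged as acceptors, so
no incidental bond can pollute the scripted residues' occupancy.

**Affinity table.** IC50 values are log-spaced over the assay's
39–100,000 nM span (the weakest compound censored, mirroring a
">100,000" bound); planted estimates are ρ·z + √(1−ρ²)·noise on the
standardized experimental ΔG, rescaled to an affinity-like range
(−30 ± 8 kcal/mol), so the population correlation equals the target
(0.63 by default at n = 12).

What the toys do **not** emulate: solvated dynamics, force-field
energetics, receptor flexibility, chemically realistic ligands, or the
published per-compound numbers (which depend on AMBER trajectories,
AutoDock scoring and PB solvations outside this package's scope).
Passing the planted-truth suite shows the *algorithms* recover known
answers under controlled conditions; it does not validate predictions on
real complexes.

## Problem sizes and determinism

Test and acceptance runs use a 10-torsion toy system, 1000-frame
trajectories at 10 ps spacing, k = 5 clusters, 12-compound affinity
tables, and 10 independent docking seeds; the weight-monotonicity check
uses a 2-torsion system over 20 seeds.  All randomness flows through
seeded `numpy` generators; identical seeds give bit-identical docking
results, trajectories and tables.

## Known limitations

* The surrogate energy is uncalibrated; its numbers are not comparable
  to published binding affinities.
* Grid interpolation degrades inside the repulsive wall (use the direct
  path when scoring clashed poses).
* The frozen-prefix growth rule means early mis-threads cannot be
  repaired mid-protocol; the beam width, rotamer scan and final polish
  mitigate but do not eliminate this on pathological systems.
* Hydrogen-bond chemistry is purely geometric; donors/acceptors must be
  flagged on input atoms.
* Normal-mode entropy uses finite differences of the energy callable and
  scales poorly beyond a few hundred atoms.
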