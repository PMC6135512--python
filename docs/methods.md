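# Methods

This note documents the models, conventions, numerical choices and known
limitations of `dimertraj`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## System model

A system is a two-monomer protein (groups `A` and `B`, author/PDB residue
numbering, 1-based, all ranges closed intervals) with up to two cofactor
copies, one per interface binding site (groups `L1`, `L2`). No bond may
cross the monomer–monomer boundary: the modeled complexes deliberately lack
the covalent Schiff-base linkage between the active-site lysine and the
PLP cofactor, so the monomers and each cofactor copy are separable
evaluation contexts. Coordinates travel as single/multi-model PDB (via
biotite) or XYZ series; force-field parameters (partial charges, LJ ε and
r_min/2, intrinsic GB radii and screening factors, LCPO coefficients,
harmonic bond/angle and torsion terms) travel in a plain-text TSV sidecar
so the artifact is self-contained without any binary engine topology.
Alternate locations and insertion codes in PDB input are rejected rather
than silently resolved.

## Geometry

Superposition is least-squares (Kabsch, SVD with proper-rotation
correction), batched across frames. RMSD series superpose each frame on a
*fit* index set and measure on a possibly different set without re-fitting;
the cofactor RMSD protocol superposes on the scaffold core Cα of both
monomers and measures the heavy atoms of each site against the reference
pose, the two sites being reported separately and their concatenation
forming the distribution (mean and SD; histogram bin width 0.05 Å).
"Distribution width" in summaries is the SD of the RMSD series — the only
moment-level statistic consistent with reporting a mean alongside.

RMSF uses the iteratively refined mean structure (fit → mean → fit until
the mean drifts < 1e-6 Å, max 100 iterations); profiles of monomers A and B
may be averaged onto one residue axis. When a mobile loop is analysed, the
superposition fit excludes the loop residues: fitting on a set that
contains a large coherently moving subset absorbs part of that motion into
the rigid-body fit and both deflates the loop RMSF and inflates everything
else. This matters at toy scale (a 18-residue loop is a large fraction of a
32-residue monomer) and is the package's standard protocol at every scale.

Finite-size caveat: superposition to the sample mean absorbs 6 rigid-body
degrees of freedom, so the RMSF of pure isotropic jitter σ per coordinate
converges to σ√3 · √(1 − 6/(3n)) for n fitted centers (≈ 3% low at n = 32).
The acceptance tolerance (5%) accounts for this.

Ring stacking fits a least-squares plane per ring (SVD normal); the
interplanar angle is arccos|n̂_A·n̂_B| ∈ [0°, 90°], and the separation is
the centroid–centroid vector projected onto the mean normal. The
loop-opening verdict compares unbound vs. bound RMSF profiles over the loop
range and requires the increase to reach the threshold (default 10 Å) at
*every* loop residue.

## Hydrogen bonds

Default geometric criteria: donor–acceptor heavy-atom distance ≤ 3.5 Å and
D–H–A angle ≥ 135° — the common MD-analysis convention; both are
configurable. On hydrogen-free topologies the heavy-atom fallback applies
the distance criterion alone and treats every N/O as both donor and
acceptor, emitting each unordered pair once. A bond's identity is the
(donor heavy atom, acceptor heavy atom) pair, so multiple hydrogens on one
donor count once per frame and occupancies are exact rationals
formed/total ≤ 1. The "cofactor-coupled" network is the candidate
restriction *one partner in a ligand group*. Network comparison aligns
bonds by (group, residue number, atom name), falling back to residue-number
matching for substituted residues; bonds with occupancy exactly 1.0 in the
reference are flagged as key bonds.

## Essential dynamics

The coordinate centers are the Cα atoms of a residue window on both
monomers plus the C6 carbon of each cofactor (for the hGOT1 numbering,
residues 40–403 on both monomers + 2 × C6 = 730 centers). Pooled frames
from all labeled systems are superposed onto the iteratively refined pooled
mean over the centers; the 3N×3N covariance of Cartesian deviations uses
1/(n−1) normalization and no mass weighting (the centers are plain atoms
counted equally). Eigenvectors are sorted by descending eigenvalue, each
oriented so its largest-|loading| coordinate is positive (eigenvector sign
is otherwise arbitrary; this fixes a reproducible "positive displacement"
direction). The model records provenance: per-system frame counts, window
and stride (default: last 800 ns at 1 frame/ns — four 1000-ns systems pool
to 3,200 frames), and the superposition protocol.

A frame's displacement along component k is the inner product of its
superposed, mean-subtracted 3N coordinate vector with eigenvector k — so
the pooled fitting frames' projection variance equals the eigenvalue
exactly, and the projection of mean + c·PC_k reads exactly c. Displacements
are reported relative to the reference system: one common offset (the
reference mean) is subtracted from every system's series.
Displacement-vs-energy scatter is summarized as axis-aligned ellipses
(componentwise mean and SD; no covariance tilt).

## Energetics

All energies are kcal/mol; no cutoff and no periodicity anywhere.

* Coulomb constant 332.0637 kcal·Å/(mol·e²); LJ in r_min/2 + ε form with
  r_min,ij = r_min/2,i + r_min/2,j and ε_ij = √(ε_i ε_j). 1-2 and 1-3
  pairs are excluded; 1-4 pairs are scaled by 1/1.2 (Coulomb) and 1/2.0
  (LJ), the AMBER convention, configurable in source constants.
* Bonded terms: E = k(r − r0)² for bonds, k(θ − θ0)² for angles, and
  V(1 + cos(nφ − γ)) for torsions.
* Generalized Born: HCT pairwise descreening integral with screened reduced
  radii (intrinsic radius minus the 0.09 Å offset, element-typed screening
  factors), including the engulfed-sphere correction, followed by the
  OBC(II) tanh rescaling 1/R_eff = 1/ρ̃ − tanh(αΨ − βΨ² + γΨ³)/ρ with
  α, β, γ = 1.0, 0.8, 4.85. Energy: −(332.0637/2)(1/ε_in − 1/ε_out)
  Σ_ij q_i q_j / f_GB over all ordered pairs including self terms, with
  f_GB = √(r² + R_i R_j exp(−r²/4R_iR_j)); ε_in = 1, ε_out = 78.5. The
  isolated-atom limit R_eff = ρ − 0.09 Å and the Born single-ion formula
  are exact limits of this implementation (verified in tests), and at 50 Å
  separation f_GB → r so two ions reduce to summed Born self terms plus a
  screened Coulomb cross term.
* Nonpolar solvation: LCPO analytical SASA (probe 1.4 Å, per-atom P1–P4
  coefficients, buried-area terms clamped to physical bounds) times a
  surface tension of 0.005 kcal/(mol·Å²), zero offset.

### EM / EE / EL / ET decomposition

Single-trajectory approximation: monomer and ligand conformations are
extracted from the complex frames (no separate component simulations).
Per frame, with Born radii recomputed for each evaluation context so that
interaction terms include GB desolvation:

* EM_i = full energy of monomer i alone; EM = EM1 + EM2
* EE = E(dimer, no ligands) − EM1 − EM2
* EL_site = E(dimer + that ligand) − E(dimer) − E(ligand alone);
  EL = EL_1 + EL_2
* ET = EM + EE + EL — definitional, so it holds to double-precision
  rounding on every frame; the published hGOT1 energy table shipped with
  the package exhibits the same identity at printed precision.

Summaries report the per-frame mean, the population SD over the schedule
(the reading of published "±" columns adopted here), and additionally a
5-block block-averaged standard error, since frame scatter and block error
answer different questions. Entropy terms are out of scope: these are
effective energies.

### Per-residue pairwise decomposition

The pairwise matrices decompose the *cross-partition interaction energy*:
Coulomb + LJ + GB cross pairs evaluated at the combined context's Born
radii (ligand-free dimer for the monomer–monomer surface; dimer + one site
for the protein–ligand surface). For monomer–monomer, each pair energy is
split half/half between its two residues; for protein–ligand, each protein
residue receives its full interaction with the cofactor. Either way the
per-residue sums reproduce the frame's total cross energy to machine
precision (the conservation checked in tests). Note this cross-interaction
total is not numerically identical to the ΔE-based EE/EL above, which
additionally contain desolvation self-energy changes that no atom-pair
term can carry; the pairwise view is the standard per-residue attribution
of the interaction surface. Variant matrices may be expressed relative to
the reference system's matrix.

## Synthetic data generator

The generator emulates, at configurable scale, the statistical features the
analyses are meant to detect — not the physics that produces them. Defaults
are the emulated study conditions: 413 residues per monomer, 1000 frames at
1 ns spacing with analyses windowing the last 800 ns, door loop at residues
15–32.

* **Geometry**: monomer A is a grid of residues (Cα + sidechain dummy, plus
  designated donor oxygens, a six-carbon stacking ring planted coplanar
  with the ligand ring at 3.8 Å, and catalytic-triad stand-ins at 3.0 Å
  pairwise spacing); monomer B is its mirror image through the interface
  plane; one 12-atom PLP-like ligand (pyridine-type ring including C6,
  hydroxyl/aldehyde oxygens, a mono-anionic phosphate-like tail — the
  protonation choice is explicit in the sidecar net-charge declaration) per
  site. The reference frame is sterically clean (every pair beyond 1-3
  bonding ≥ 2.0 Å) and is the equilibrium geometry of the toy force field
  (uniform k = 300 kcal/mol/Å² bonds with r0 taken from the reference).
* **Interface mode**: rigid counter-rotation of the two monomer cores
  (residue fraction 0.19–0.73 of the chain), stored as an explicit 3N
  vector whose restriction to the analysis centers (all Cα + C6) is
  orthogonalized against that subset's six rigid-body modes and normalized
  to unit length — a least-squares superposition of the centers therefore
  cannot absorb the motion, and the planted amplitude is recoverable
  *as-is* as a displacement in Å. Amplitudes are drawn per frame from
  Normal(mean_label, SD); default means follow the pattern reference 0,
  two variants −δ, one variant +2δ with δ = 3 Å and SD = 1.5 Å (the sign
  pattern of the emulated study; the magnitude is a toy choice that keeps
  mode variance well above jitter).
* **Loop opening**: after an onset at fraction 0.1 of the run (the emulated
  closed→open transition happens early), loop atoms receive a coherent
  per-frame Gaussian z-displacement whose SD is the "opening" parameter —
  so the parameter directly controls the loop RMSF increase (12 Å planted
  ⇒ ≈ 11–12 Å measured increase against a bound run).
* **Hydrogen bonds**: per site, four static donors rest at the formed pose
  (2.9 Å from their designated acceptor) and two switching donors toggle
  between formed (2.9 Å) and broken (5.5 Å) poses via a two-state Markov
  chain with per-frame probabilities k_on = 0.3, k_off = 0.1 → stationary
  occupancy 0.75. Note the chain is autocorrelated (ρ = 1 − k_on − k_off =
  0.6), so the sampling SD of an 800-frame occupancy is about twice the
  binomial SE — relevant when choosing tolerances.
* **Jitter**: iid Gaussian σ = 0.15 Å on every coordinate, applied last.
  Chosen so the two hydrogen-bond poses stay cleanly separated relative to
  the 3.5 Å criterion (the formed-pose distance fluctuates with SD ≈ σ√2 ≈
  0.21 Å against a 0.6 Å margin); RMSF calibration tests override it to
  0.5 Å explicitly.
* **Determinism**: one RNG stream per (seed, system label) via a CRC-based
  seed sequence; identical spec + seed reproduce trajectories bitwise.

What passing tests on this generator do and do not show: they validate the
estimators (superposition, occupancy accounting, covariance
eigenstructure, energy bookkeeping) against exact ground truth; they say
nothing about force-field accuracy, sampling convergence, or solvent
models on real proteins, because the toy data contain none of those
difficulties (no anharmonicity, no correlated solvent motion, no
conformational substates beyond the planted ones).

## Pipeline

The config (YAML, pydantic-validated) declares systems (topology, sidecar,
trajectory each), exactly one reference label, the frame schedule, the PCA
residue window, optional loop/stacking/triad observables, hydrogen-bond
criteria, and the output directory. Stages run in a fixed order (load →
geometry → hbond → essential dynamics → energetics → summary); a stage
failure aborts with the stage name and the manifest flags the run
incomplete. All stage outputs are CSV/JSON with a fixed float format; the
manifest records SHA-256 hashes of every input and output, so determinism
is checkable by hash comparison. The summary is assembled by reading stage
output files, never by recomputation. The ligand-free-style system
(`unbound_label`) participates only in the geometry stage's loop
comparison.

Problem sizes: the shipped demo uses a 48-residue-per-monomer toy dimer
with 250 frames (analysis window 200 ns) — the scale at which the full
pipeline, including the O(n²) per-frame GB evaluations of seven contexts,
runs in a few minutes on one CPU; the test suite uses 16–32 residues and
60–800 frames per check. Acceptance-style checks that depend only on
counting (the 730-center selection, the 3,200 pooled frames) use the
full-size residue numbering, which costs nothing.

## Known limitations

* The toy force field is not physical; energy magnitudes from synthetic
  data are bookkeeping quantities, meaningful only through their identities
  and invariances.
* GB/LCPO are all-pairs O(n²) per frame with no neighbor lists; fine for
  toy systems and post-processing-scale selections, not for large proteins
  at every frame.
* The pairwise energy matrices attribute only cross-partition interaction
  terms (see above); desolvation self-energy shifts are visible in EE/EL
  but not attributable to residue pairs by construction.
* Heavy-atom hydrogen-bond mode cannot apply the angle criterion; explicit
  hydrogens are honoured when present but the synthetic topologies do not
  generate them.
* PDB parsing intentionally rejects altlocs and insertion codes; no
  protonation assignment or missing-atom reconstruction is attempted.
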