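# dimertraj

Trajectory analysis for homodimeric enzymes whose cofactor sits at the
dimer interface — written around the case of human cytosolic aspartate
aminotransferase (hGOT1/AAT), a homodimer with one pyridoxal 5′-phosphate
(PLP) molecule bound in each of its two interface active sites. Disease
variants of such enzymes (e.g. E266K, R267H, P300L in hGOT1) can misalign
the dimer interface and weaken cofactor binding; this package provides the
analysis machinery to quantify that from molecular-dynamics trajectories:

* **Geometry** — Kabsch superposition, RMSD series (fit on the protein
  core, measure the cofactor), per-residue RMSF with monomer averaging,
  distance series, π–π ring-stacking metrics (interplanar distance and
  angle), and detection of the P15–R32 "door"-loop opening from
  bound/unbound RMSF profiles.
* **Hydrogen bonds** — geometric detection (donor–acceptor ≤ 3.5 Å,
  D–H–A ≥ 135°, heavy-atom fallback), exact per-bond occupancies over a
  trajectory, and occupancy-network comparison of variants against a
  reference system.
* **Essential dynamics** — pooled PCA over several labeled trajectories:
  the Cα atoms of a residue window on both monomers plus the C6 carbon of
  each cofactor form the coordinate centers; eigen-decomposition of the
  3N×3N Cartesian covariance gives the collective modes, and the scalar
  projection of each frame onto PC1 (zeroed on the reference system's mean)
  is the dimer-misalignment displacement statistic.
* **Energetics** — implicit-solvent MM-GB/SA post-processing authored
  in-package: exact no-cutoff Coulomb and Lennard-Jones sums, harmonic
  bonded terms, generalized Born with OBC(II) effective radii
  (α, β, γ = 1.0, 0.8, 4.85), LCPO analytical surface area, and the
  decomposition into monomer (EM = EM1 + EM2), dimerization (EE), and
  cofactor-binding (EL, summed over both sites) energies with the
  definitional total **ET = EM + EE + EL**, plus a per-residue pairwise
  breakdown of EE and EL.
* **Synthetic data** — a toy-dimer generator that plants known structure
  (an orthonormal interface-rotation mode with system-dependent mean
  displacement, a loop-opening event, two-state Markov hydrogen bonds,
  Gaussian jitter) so every analysis stage can be validated against exact
  ground truth without an MD engine.

## Worked example

Create a synthetic four-system workspace (reference WT + three variants,
plus a ligand-free-style run with a planted loop opening) and run the full
pipeline:

```sh
dimertraj demo --outdir demo --seed 1 --residues 32 --frames 120 --window 100
dimertraj run  --config demo/config.yaml
dimertraj report --outdir demo/out
```

which prints (numbers from this exact invocation):

```
systems: WT, E266K, R267H, P300L (reference WT)
pooled PCA frames: 400 over 66 coordinate centers
mean PC1 displacement (A, reference zeroed):
     E266K: -3.11
     P300L: -3.07
     R267H: +6.00
        WT: -0.00
cofactor RMSD (A):
        WT: 0.33 +- 0.08
     E266K: 0.32 +- 0.06
     R267H: 0.39 +- 0.13
     P300L: 0.33 +- 0.09
    WT_apo: 0.33 +- 0.08
effective energies (kcal/mol):
        WT: EM 2710.77  EE 5.79  EL 128.75  ET 2845.31
     E266K: EM 3350.01  EE 6.02  EL 100.22  ET 3456.25
     R267H: EM 4855.54  EE 5.45  EL 98.12  ET 4959.11
     P300L: EM 3140.44  EE 6.03  EL 106.43  ET 3252.91
loop opening detected: True
```

Reading the output: the generator planted per-system mean displacements of
0, −3, +6, −3 Å along the interface mode; the pooled PCA recovers exactly
that pattern (one variant displaced positively, two negatively, the
reference at zero). The cofactor RMSD is the heavy-atom RMSD of each PLP
site after superposing on the scaffold core Cα. The energy table is the
EM/EE/EL/ET decomposition of the toy force field — the magnitudes are toy
numbers, but the identity ET = EM + EE + EL holds to machine precision per
frame, exactly as it does in the published hGOT1 energy table shipped with
the package (`dimertraj.load_reference_energy_table()`). The loop verdict
compares unbound vs. bound RMSF over the door-loop residues against the
10 Å opening criterion.

Every stage also writes CSV/JSON files under `demo/out/` (RMSF profiles,
occupancy tables, the PC model, displacement series, pairwise energy
matrices) plus `manifest.json` with SHA-256 hashes of all inputs and
outputs; reruns with the same seed are byte-identical.

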