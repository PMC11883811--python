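# bindmode

Consensus inference and evaluation of protein–protein binding modes from
multi-engine docking poses, with downstream interface and trajectory
analysis:

- **structure_io** — PDB read/write (author residue numbering preserved,
  altlocs resolved by occupancy), residue-range truncation, atom selection.
- **pose_consensus** — pose pooling under `X-m-n` labels (engine / model
  rank / refinement rank), 2–10 Å interface distance restraints, Kabsch
  superposition onto a common receptor frame, pairwise heavy-atom RMSD,
  agglomerative clustering with Kelley–Gardner–Sutcliffe penalty selection
  of the cluster count, centroid-of-most-populated-cluster consensus and
  per-engine contribution percentages.
- **interface_analysis** — typed contact detection (H-bond, salt bridge,
  π-stacking, aromatic H-bond) with configurable geometric criteria,
  interface residue scans, per-frame distance monitors (including group
  targets such as a γ-phosphate), contact occupancy over trajectories
  (stable at ≥ 50%), and single-linkage hot-region grouping of hotspots.
- **trajectory_metrics** — per-frame RMSD with a sliding-window convergence
  call, per-residue RMSF about the superposed mean structure, strided
  trajectory clustering with medoid representative extraction.
- **binding_energy** — declared surrogate end-point energy (12-6
  Lennard-Jones, formal-charge Coulomb under ε(r) = 4r, per-H-bond and
  per-apolar-contact rewards) with the single-trajectory convention, so
  ΔG_bind = G_complex − G_receptor − G_ligand reduces to the
  cross-interface sum; per-frame trajectory averaging (mean ± SE),
  side-chain-truncation alanine scanning and Borda-consensus hotspot
  ranking across scorers.
- **synthetic_data** — seeded generators for toy two-chain complexes with
  planted contacts (salt bridge / H-bond / hydrophobic patch), multi-engine
  pose ensembles with a planted true mode plus decoys, and jittered
  trajectories with optional breathing drift.

The surrogate energy is *not* an MM-GBSA implementation; absolute
magnitudes are not comparable to published force-field values. All
analyses run end-to-end on synthetic inputs with no downloads.

## CLI

```bash
bindmode synth --seed 7 outdir/                      # toy complex + poses + trajectory
bindmode struct truncate --keep A:1537-1730 in.pdb out.pdb
bindmode consensus --receptor-pdb rec.pdb --restraints restraints.json \
    manifest.tsv outdir/                             # manifest: path/engine/m/n TSV
bindmode interface --monitor "A:1643:ND2--GTP:gamma-phosphate" \
    complex.pdb traj.pdb outdir/
bindmode energy --stride-ns 2 complex.pdb traj.pdb outdir/
bindmode alascan --residues auto-interface complex.pdb outdir/
bindmode pipeline --seed 7 outdir/                   # full deterministic run
```

Trajectories are multi-model PDB files. Chain roles default to A = receptor,
B = ligand (`--receptor-chains/--ligand-chains` to override); cofactor
chains travel with the ligand side.

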