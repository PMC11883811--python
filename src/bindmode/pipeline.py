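"""Deterministic end-to-end run on synthetic inputs.

Generates a toy complex, a multi-engine pose ensemble and a jittered
trajectory for one seed, executes consensus -> interface -> trajectory ->
energy -> alanine scan, and writes every declared artifact (TSV/PDB/JSON)
with fixed float formatting so identical seeds give byte-identical output.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import binding_energy as be
from . import interface_analysis as ia
from . import pose_consensus as pc
from . import synthetic_data as sd
from . import trajectory_metrics as tm
from .structure_io import Structure, write_structure, write_trajectory

__all__ = ["run_pipeline"]

F = "{:.6f}".format


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(F(v) if isinstance(v, float) else str(v)
                               for v in row))
    path.write_text("\n".join(lines) + "\n")


def _merge(receptor: Structure, ligand: Structure, id: str) -> Structure:
    merged = Structure(list(receptor.atoms) + list(ligand.atoms), id=id,
                       chain_partition={})
    merged.chain_partition = {**receptor.chain_partition,
                              **ligand.chain_partition}
    for a in merged.atoms:
        merged.chain_partition.setdefault(
            a.chain_id,
            "receptor" if a.chain_id in {x.chain_id for x in receptor.atoms}
            else "ligand")
    return merged


def run_pipeline(seed: int, outdir: str | Path, *,
                 n_frames: int = 40, jitter_sd: float = 0.25) -> dict:
    """Run the full analysis for one seed; returns a summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- synthetic inputs -------------------------------------------------
    toy_spec = sd.ToySpec(seed=seed)
    complex, truth_contacts = sd.build_toy_complex(toy_spec)
    write_structure(complex, outdir / "complex.pdb")
    (outdir / "truth.json").write_text(json.dumps(
        [{"kind": t.kind, "receptor_residue": list(t.receptor_residue),
          "ligand_residue": list(t.ligand_residue), "distance": t.distance}
         for t in truth_contacts], indent=2, sort_keys=True) + "\n")

    ens_spec = sd.EnsembleSpec(seed=seed)
    ensemble, truth_record = sd.generate_pose_ensemble(complex, ens_spec)

    # --- consensus --------------------------------------------------------
    ensemble = pc.superpose_on_receptor(ensemble, ensemble.receptor)
    matrix = pc.rmsd_matrix(ensemble, "ligand-heavy")
    clustering = pc.kelley_optimal_k(matrix)
    clustering = pc.consensus_pose(ensemble, clustering)
    _write_tsv(outdir / "clusters.tsv", ["label", "cluster"],
               [[lab, clustering.partition[lab]] for lab in clustering.labels])
    _write_tsv(outdir / "penalty.tsv", ["k", "penalty"],
               [[k, v] for k, v in sorted(clustering.penalty_curve.items())])
    _write_tsv(outdir / "contributions.tsv", ["engine", "percent"],
               [[e, p] for e, p in sorted(clustering.contributions.items())])
    centroid = next(p for p in ensemble.poses
                    if p.label == clustering.centroid_label)
    consensus = _merge(ensemble.receptor,
                       ensemble.ligand_template.with_coords(
                           centroid.ligand_coords),
                       id=f"consensus-{seed}")
    write_structure(consensus, outdir / "consensus.pdb")

    # --- restraints on the consensus pose --------------------------------
    restraint = pc.Restraint(
        receptor_residues=[t.receptor_residue for t in truth_contacts],
        ligand_residues=[t.ligand_residue for t in truth_contacts])
    report = pc.check_restraints(
        ensemble.receptor,
        ensemble.ligand_template.with_coords(centroid.ligand_coords),
        restraint)
    _write_tsv(outdir / "restraints.tsv",
               ["side", "chain", "residue", "min_distance", "satisfied"],
               [[side, c, n, d, ok]
                for (side, c, n), (d, ok) in sorted(report.per_residue.items())])

    # --- trajectory -------------------------------------------------------
    traj = sd.generate_trajectory(complex, n_frames=n_frames,
                                  jitter_sd=jitter_sd, seed=seed)
    write_trajectory(traj.topology, traj.frames, outdir / "trajectory.pdb")
    series = tm.rmsd_series(traj, reference=0, selection="ca",
                            window_ns=5.0)
    _write_tsv(outdir / "rmsd.tsv", ["time_ns", "rmsd"],
               [[F(t), r] for t, r in zip(series.times_ns, series.values)])
    profile = tm.rmsf_per_residue(traj)
    _write_tsv(outdir / "rmsf.tsv", ["chain", "residue", "rmsf"],
               [[c, n, v] for (c, n), v in zip(profile.residues,
                                               profile.values)])
    tclust = tm.cluster_trajectory(traj, stride=5, max_clusters=10)
    write_structure(traj.frame_structure(tclust.representative),
                    outdir / "representative.pdb")

    # --- interface --------------------------------------------------------
    interactions = ia.detect_interactions(complex)
    _write_tsv(outdir / "interactions.tsv",
               ["type", "rec_chain", "rec_res", "rec_name", "lig_chain",
                "lig_res", "lig_name", "atoms", "distance"],
               [[r.type, *r.receptor_residue, *r.ligand_residue,
                 "|".join(r.atoms), r.distance] for r in interactions])
    occupancy = ia.interaction_occupancy(complex, traj.frames)
    _write_tsv(outdir / "occupancy.tsv",
               ["type", "rec_res", "lig_res", "occupancy", "mean_distance",
                "sd_distance", "stable"],
               [[o.type, f"{o.receptor_residue[0]}:{o.receptor_residue[1]}",
                 f"{o.ligand_residue[0]}:{o.ligand_residue[1]}",
                 o.occupancy, o.mean_distance, o.sd_distance, o.stable]
                for o in occupancy])
    sb = next(t for t in truth_contacts if t.kind == "salt_bridge")
    series_d = ia.monitor_distance(
        complex, traj.frames,
        f"{sb.receptor_residue[0]}:{sb.receptor_residue[1]}:NZ",
        f"{sb.ligand_residue[0]}:{sb.ligand_residue[1]}:OE1")
    _write_tsv(outdir / "distances.tsv", ["frame", "distance"],
               [[i, d] for i, d in enumerate(series_d.distances)])

    # --- energy and alanine scan -----------------------------------------
    model = be.EnergyModel()
    summary = be.trajectory_binding_energy(traj, model, stride_ns=2.0)
    _write_tsv(outdir / "energy.tsv",
               ["frame", "dG_bind", "dG_vdW", "dG_elec", "dG_Hbond", "dG_Lipo"],
               [[f, e.dG_bind, e.dG_vdW, e.dG_elec, e.dG_Hbond, e.dG_Lipo]
                for f, e in zip(summary.frame_indices, summary.per_frame)])
    iface = ia.interface_residues(complex)
    scan_residues = sorted(iface["receptor"] | iface["ligand"])
    table = be.alanine_scan(complex, scan_residues, model)
    _write_tsv(outdir / "hotspots.tsv",
               ["chain", "residue", "ddG", "is_hotspot"],
               [[c, n, table.ddG[(c, n)], table.is_hotspot[(c, n)]]
                for c, n in sorted(table.ddG)])
    hot = [r for r, flag in table.is_hotspot.items() if flag]
    if hot:
        regions = ia.hot_regions(hot, complex)
        _write_tsv(outdir / "hot_regions.tsv",
                   ["region", "chain", "residue"],
                   [[r.region_id, c, n] for r in regions for c, n in r.members])

    return {
        "seed": seed,
        "optimal_k": clustering.optimal_k,
        "centroid_label": clustering.centroid_label,
        "contributions": clustering.contributions,
        "restraints_satisfied": report.satisfied,
        "mean_dG": summary.mean_dG,
        "n_interactions": len(interactions),
        "n_hotspots": len(hot),
    }
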