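"""Multi-engine docking-pose pooling and consensus binding-mode selection.

Workflow: pool poses labelled ``X-m-n`` (engine X, model rank m, refinement
rank n), check interface distance restraints, superpose every pose's receptor
frame onto a common reference, build a pairwise heavy-atom RMSD matrix,
cluster agglomeratively, pick the cluster count with the Kelley-Gardner-
Sutcliffe penalty, and report the pose nearest the centroid of the most
populated cluster together with per-engine contribution percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist, squareform

from .geometry import kabsch, pairwise_rmsd_matrix
from .structure_io import Structure, StructureError, read_structure

__all__ = [
    "PoseRecord", "PoseEnsemble", "Restraint", "RestraintReport",
    "RMSDMatrix", "ClusteringResult",
    "check_restraints", "superpose_on_receptor", "rmsd_matrix",
    "kelley_optimal_k", "consensus_pose", "load_manifest",
]


@dataclass(frozen=True)
class PoseRecord:
    """One docked ligand placement with its provenance."""

    ligand_coords: np.ndarray  # (n_ligand_atoms, 3), Angstrom
    engine: str
    model_rank: int
    refinement_rank: int
    fit_rmsd: float | None = None  # receptor-fit residual after superposition

    def __post_init__(self) -> None:
        c = np.asarray(self.ligand_coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError(f"ligand coordinate block has shape {c.shape}")
        object.__setattr__(self, "ligand_coords", c)
        if not (1 <= int(self.model_rank)):
            raise ValueError("model_rank must be >= 1")
        if not (1 <= int(self.refinement_rank)):
            raise ValueError("refinement_rank must be >= 1")

    @property
    def label(self) -> str:
        return f"{self.engine}-{self.model_rank}-{self.refinement_rank}"


@dataclass
class PoseEnsemble:
    """Pose set sharing one receptor frame and one ligand atom template."""

    receptor: Structure
    ligand_template: Structure
    poses: list[PoseRecord]

    def __post_init__(self) -> None:
        if not self.poses:
            raise ValueError("ensemble needs at least one pose")
        n = self.ligand_template.n_atoms
        for p in self.poses:
            if p.ligand_coords.shape[0] != n:
                raise ValueError(
                    f"pose {p.label}: {p.ligand_coords.shape[0]} atoms, "
                    f"ligand template has {n}")

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.poses]

    def ligand_structure(self, pose: PoseRecord) -> Structure:
        return self.ligand_template.with_coords(pose.ligand_coords)


@dataclass(frozen=True)
class Restraint:
    """Interface distance restraint between named residues of both partners.

    A restrained residue is satisfied when its minimum heavy-atom distance to
    any restrained residue of the partner lies within [lower, upper].
    """

    receptor_residues: frozenset[tuple[str, int]]
    ligand_residues: frozenset[tuple[str, int]]
    lower: float = 2.0
    upper: float = 10.0

    def __init__(self, receptor_residues: Iterable, ligand_residues: Iterable,
                 lower: float = 2.0, upper: float = 10.0):
        object.__setattr__(self, "receptor_residues",
                           frozenset((str(c), int(n)) for c, n in receptor_residues))
        object.__setattr__(self, "ligand_residues",
                           frozenset((str(c), int(n)) for c, n in ligand_residues))
        object.__setattr__(self, "lower", float(lower))
        object.__setattr__(self, "upper", float(upper))
        if not (0 < self.lower < self.upper):
            raise ValueError("need 0 < lower < upper")


@dataclass
class RestraintReport:
    per_residue: dict[tuple[str, str, int], tuple[float, bool]]
    satisfied: bool

    @property
    def violations(self) -> list[tuple[str, str, int]]:
        return [k for k, (_, ok) in self.per_residue.items() if not ok]


@dataclass
class RMSDMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("RMSD matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-9) or np.any(v < -1e-12):
            raise ValueError("RMSD matrix must have zero diagonal, nonnegative")
        self.values = v


@dataclass
class ClusteringResult:
    labels: list[str]
    linkage_matrix: np.ndarray          # scipy dendrogram encoding
    penalty_curve: dict[int, float]     # k -> Kelley penalty
    optimal_k: int
    partition: dict[str, int]           # pose label -> cluster id (1-based)
    matrix: RMSDMatrix
    most_populated: int | None = None
    centroid_label: str | None = None
    contributions: dict[str, float] = field(default_factory=dict)

    def cluster_members(self, cluster_id: int) -> list[str]:
        return [lab for lab in self.labels if self.partition[lab] == cluster_id]


# ---------------------------------------------------------------------------
# Restraint checking
# ---------------------------------------------------------------------------

def _residue_heavy_coords(s: Structure, residues: Iterable[tuple[str, int]]
                          ) -> dict[tuple[str, int], np.ndarray]:
    table: dict[tuple[str, int], list[np.ndarray]] = {}
    for a in s.atoms:
        key = (a.chain_id, a.residue_number)
        if a.is_heavy and key in residues:
            table.setdefault(key, []).append(a.coords)
    missing = set(residues) - set(table)
    if missing:
        pretty = ", ".join(f"{c}:{n}" for c, n in sorted(missing))
        raise StructureError(f"restrained residue(s) not found: {pretty}")
    return {k: np.array(v) for k, v in table.items()}


def check_restraints(receptor: Structure, ligand: Structure,
                     r: Restraint) -> RestraintReport:
    """Evaluate the 2-10 A style interface restraints on one pose.

    ``ligand`` is the posed ligand structure (use
    ``PoseEnsemble.ligand_structure`` for a PoseRecord).
    """
    rec = _residue_heavy_coords(receptor, r.receptor_residues)
    lig = _residue_heavy_coords(ligand, r.ligand_residues)
    rec_all = np.vstack(list(rec.values()))
    lig_all = np.vstack(list(lig.values()))
    report: dict[tuple[str, str, int], tuple[float, bool]] = {}
    for (c, n), xyz in sorted(rec.items()):
        d = float(cdist(xyz, lig_all).min())
        report[("receptor", c, n)] = (d, r.lower <= d <= r.upper)
    for (c, n), xyz in sorted(lig.items()):
        d = float(cdist(xyz, rec_all).min())
        report[("ligand", c, n)] = (d, r.lower <= d <= r.upper)
    return RestraintReport(report, all(ok for _, ok in report.values()))


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def superpose_on_receptor(ensemble: PoseEnsemble,
                          reference_receptor: Structure) -> PoseEnsemble:
    """Rigid-fit the ensemble's receptor frame onto a reference receptor.

    The correspondence is by (chain, residue number, insertion code, atom
    name); the resulting transform is applied to the receptor and to every
    pose's ligand coordinates, and the receptor-fit RMSD is recorded on each
    pose.
    """
    ref_index = {a.residue_key + (a.name,): a.coords
                 for a in reference_receptor.atoms}
    mobile, target = [], []
    for a in ensemble.receptor.atoms:
        key = a.residue_key + (a.name,)
        if key in ref_index:
            mobile.append(a.coords)
            target.append(ref_index[key])
    if len(mobile) < 3:
        raise StructureError(
            f"only {len(mobile)} correspondence atoms between receptor frames")
    try:
        transform, fit = kabsch(np.array(mobile), np.array(target))
    except ValueError as exc:
        raise StructureError(str(exc)) from exc
    new_receptor = ensemble.receptor.with_coords(
        transform.apply(ensemble.receptor.coords))
    new_poses = [replace(p, ligand_coords=transform.apply(p.ligand_coords),
                         fit_rmsd=fit)
                 for p in ensemble.poses]
    return PoseEnsemble(new_receptor, ensemble.ligand_template, new_poses)


# ---------------------------------------------------------------------------
# RMSD matrix
# ---------------------------------------------------------------------------

def rmsd_matrix(ensemble: PoseEnsemble,
                selection: str = "ligand-heavy") -> RMSDMatrix:
    """Pairwise pose RMSD with no per-pair refitting.

    ``ligand-heavy`` (default) measures ligand displacement in the shared
    receptor frame, which is what distinguishes binding modes; ``all-heavy``
    additionally includes the (shared, hence constant) receptor atoms and
    reproduces the literal complex-wide reading.
    """
    heavy_idx = [i for i, a in enumerate(ensemble.ligand_template.atoms)
                 if a.is_heavy]
    if not heavy_idx:
        raise StructureError("ligand template has no heavy atoms")
    blocks = np.stack([p.ligand_coords[heavy_idx] for p in ensemble.poses])
    if selection == "ligand-heavy":
        mat = pairwise_rmsd_matrix(blocks)
    elif selection == "all-heavy":
        rec_heavy = np.array([a.coords for a in ensemble.receptor.atoms
                              if a.is_heavy])
        full = np.concatenate(
            [np.repeat(rec_heavy[None], len(ensemble.poses), axis=0), blocks],
            axis=1)
        mat = pairwise_rmsd_matrix(full)
    else:
        raise ValueError(f"unknown selection {selection!r}")
    return RMSDMatrix(ensemble.labels, mat)


# ---------------------------------------------------------------------------
# Kelley penalty cluster-count selection
# ---------------------------------------------------------------------------

def _partition_at_k(Z: np.ndarray, k: int) -> np.ndarray:
    return hierarchy.fcluster(Z, t=k, criterion="maxclust")


def _average_spread(values: np.ndarray, assignment: np.ndarray) -> float:
    """Mean over non-singleton clusters of their mean pairwise RMSD."""
    spreads = []
    for cid in np.unique(assignment):
        members = np.flatnonzero(assignment == cid)
        if len(members) < 2:
            continue
        sub = values[np.ix_(members, members)]
        iu = np.triu_indices(len(members), k=1)
        spreads.append(float(sub[iu].mean()))
    return float(np.mean(spreads)) if spreads else 0.0


def kelley_penalty_curve(matrix: RMSDMatrix, Z: np.ndarray
                         ) -> dict[int, float]:
    """Kelley-Gardner-Sutcliffe penalty for every dendrogram level.

    Average within-cluster spread is computed at each level k = 1..N-1,
    min-max normalized onto [1, N-1] across levels, and penalized by adding
    the cluster count: penalty(k) = normalized_spread(k) + k. Levels whose
    clusters are all singletons take spread 0 before normalization.
    """
    N = len(matrix.labels)
    ks = list(range(1, N))
    spreads = np.array([_average_spread(matrix.values, _partition_at_k(Z, k))
                        for k in ks])
    lo, hi = spreads.min(), spreads.max()
    if hi - lo < 1e-12:
        norm = np.ones_like(spreads)
    else:
        norm = (spreads - lo) / (hi - lo) * (N - 2) + 1.0
    return {k: float(n + k) for k, n in zip(ks, norm)}


def kelley_optimal_k(matrix: RMSDMatrix,
                     linkage: str = "average") -> ClusteringResult:
    """Agglomerative clustering with Kelley-penalty cluster-count selection.

    The optimum is the argmin of the penalty over k in [2, N-1] (lowest k on
    ties, so relabeling poses cannot change the result).
    """
    if linkage not in ("average", "complete", "ward"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    N = len(matrix.labels)
    if N < 3:
        raise ValueError("need at least 3 poses for cluster-count selection")
    condensed = squareform(matrix.values, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    curve = kelley_penalty_curve(matrix, Z)
    candidates = [k for k in sorted(curve) if 2 <= k <= N - 1]
    optimal_k = min(candidates, key=lambda k: (curve[k], k))
    assignment = _partition_at_k(Z, optimal_k)
    partition = {lab: int(c) for lab, c in zip(matrix.labels, assignment)}
    return ClusteringResult(
        labels=list(matrix.labels), linkage_matrix=Z, penalty_curve=curve,
        optimal_k=int(optimal_k), partition=partition, matrix=matrix)


# ---------------------------------------------------------------------------
# Consensus pose
# ---------------------------------------------------------------------------

def consensus_pose(ensemble: PoseEnsemble,
                   clustering: ClusteringResult) -> ClusteringResult:
    """Complete a clustering with most-populated cluster, centroid, shares.

    Ties on cluster size fall to the cluster with the smaller mean
    intra-cluster RMSD, then to the one holding the lexicographically lowest
    label; centroid ties fall to the lowest label. Contributions are engine
    percentages within the winning cluster.
    """
    if set(clustering.labels) != set(ensemble.labels):
        raise ValueError("clustering was not computed on this ensemble")
    values = clustering.matrix.values
    pos = {lab: i for i, lab in enumerate(clustering.labels)}

    def cluster_stats(cid: int):
        members = clustering.cluster_members(cid)
        idx = [pos[m] for m in members]
        if len(idx) > 1:
            sub = values[np.ix_(idx, idx)]
            iu = np.triu_indices(len(idx), k=1)
            spread = float(sub[iu].mean())
        else:
            spread = 0.0
        return members, spread

    cluster_ids = sorted(set(clustering.partition.values()))
    best = min(cluster_ids,
               key=lambda cid: (-len(clustering.cluster_members(cid)),
                                cluster_stats(cid)[1],
                                min(clustering.cluster_members(cid))))
    members, _ = cluster_stats(best)
    midx = [pos[m] for m in members]
    sub = values[np.ix_(midx, midx)]
    cost = (sub ** 2).sum(axis=1)
    order = sorted(range(len(members)), key=lambda i: (cost[i], members[i]))
    centroid_label = members[order[0]]

    by_engine: dict[str, int] = {}
    engine_of = {p.label: p.engine for p in ensemble.poses}
    for m in members:
        by_engine[engine_of[m]] = by_engine.get(engine_of[m], 0) + 1
    total = len(members)
    contributions = {eng: 100.0 * cnt / total
                     for eng, cnt in sorted(by_engine.items())}

    clustering.most_populated = int(best)
    clustering.centroid_label = centroid_label
    clustering.contributions = contributions
    return clustering


# ---------------------------------------------------------------------------
# Manifest input
# ---------------------------------------------------------------------------

def load_manifest(path: str | Path, receptor: Structure,
                  ligand_chains: Sequence[str]) -> PoseEnsemble:
    """Build a PoseEnsemble from a TSV manifest of pose PDB files.

    Columns: path, engine, model_rank, refinement_rank. Each pose file must
    contain the ligand chains congruent with the first pose (the template).
    """
    path = Path(path)
    rows = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] in ("path", "file"):
            continue
        if len(parts) < 4:
            raise StructureError(f"{path}:{ln}: expected 4 tab-separated fields")
        rows.append((parts[0], parts[1], int(parts[2]), int(parts[3])))
    if not rows:
        raise StructureError(f"manifest {path} lists no poses")
    template: Structure | None = None
    poses = []
    for file, engine, m, n in rows:
        pose_path = Path(file)
        if not pose_path.is_absolute():
            pose_path = path.parent / pose_path
        s = read_structure(pose_path)
        lig_idx = [i for i, a in enumerate(s.atoms) if a.chain_id in ligand_chains]
        if not lig_idx:
            raise StructureError(f"{file}: no atoms on ligand chains")
        lig = s.subset(lig_idx)
        if template is None:
            template = lig
            template.chain_partition = {c: "ligand" for c in ligand_chains}
        poses.append(PoseRecord(lig.coords, engine, m, n))
    assert template is not None
    return PoseEnsemble(receptor, template, poses)
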