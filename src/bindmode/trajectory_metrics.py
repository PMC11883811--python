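"""Per-frame RMSD, per-residue RMSF, convergence calling and trajectory
clustering with representative-frame extraction."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform

from .geometry import kabsch, pairwise_rmsd_matrix, rmsd
from .pose_consensus import RMSDMatrix, kelley_optimal_k
from .structure_io import Structure, StructureError, select_atoms, heavy, name

__all__ = ["Trajectory", "RMSDSeries", "RMSFProfile",
           "rmsd_series", "rmsf_per_residue", "cluster_trajectory",
           "TrajectoryClustering"]


@dataclass
class Trajectory:
    """Coordinate-frame series over a fixed topology; uniform time spacing."""

    topology: Structure
    frames: np.ndarray           # (n_frames, n_atoms, 3)
    dt_ns: float = 1.0           # time between frames

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 3 or f.shape[1:] != (self.topology.n_atoms, 3):
            raise StructureError(
                f"frames shape {f.shape} incompatible with topology")
        if f.shape[0] < 2:
            raise StructureError("trajectory needs at least 2 frames")
        self.frames = f

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_ns

    def frame_structure(self, index: int) -> Structure:
        return self.topology.with_coords(self.frames[index])


@dataclass
class RMSDSeries:
    times_ns: np.ndarray
    values: np.ndarray
    converged_at_ns: float | None


@dataclass
class RMSFProfile:
    """Per-residue fluctuation about the superposed mean structure."""

    residues: list[tuple[str, int]]
    values: np.ndarray

    def as_dict(self) -> dict[tuple[str, int], float]:
        return {r: float(v) for r, v in zip(self.residues, self.values)}


def _selection_indices(topology: Structure, selection) -> list[int]:
    if selection is None or selection == "heavy":
        return select_atoms(topology, heavy())
    if selection == "ca":
        return select_atoms(topology, name("CA"))
    if isinstance(selection, (list, tuple, np.ndarray)):
        return [int(i) for i in selection]
    raise StructureError(f"unknown selection {selection!r}")


def rmsd_series(traj: Trajectory, reference: Structure | int = 0,
                selection="ca", window_ns: float = 20.0,
                tolerance: float = 0.5) -> RMSDSeries:
    """RMSD of every frame to a reference after Kabsch superposition.

    ``converged_at_ns`` is the earliest time from which each subsequent
    sliding-window mean differs from the first converged window's mean by
    less than ``tolerance`` through the end of the trajectory; ``None`` if
    no such window exists. This is a declared formal surrogate for
    by-inspection convergence calls.
    """
    idx = _selection_indices(traj.topology, selection)
    if not idx:
        raise StructureError("empty selection")
    if isinstance(reference, int):
        ref_coords = traj.frames[reference][idx]
    else:
        ref_idx = _selection_indices(reference, selection)
        if len(ref_idx) != len(idx):
            raise StructureError("selection mismatch with reference structure")
        ref_coords = reference.coords[ref_idx]
    vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        transform, fit = kabsch(traj.frames[f][idx], ref_coords)
        vals[f] = fit
    converged = _converged_at(vals, traj.dt_ns, window_ns, tolerance)
    return RMSDSeries(traj.times_ns, vals, converged)


def _converged_at(vals: np.ndarray, dt_ns: float, window_ns: float,
                  tolerance: float) -> float | None:
    w = max(1, int(round(window_ns / dt_ns)))
    if w > len(vals):
        w = len(vals)
    means = np.array([vals[i:i + w].mean() for i in range(len(vals) - w + 1)])
    # at least two windows must agree, else the last window converges vacuously
    for i in range(len(means) - 1):
        if np.all(np.abs(means[i:] - means[i]) < tolerance):
            return float(i * dt_ns)
    return None


def rmsf_per_residue(traj: Trajectory, selection="ca",
                     superpose: bool = True,
                     superposition_rounds: int = 2) -> RMSFProfile:
    """RMSF_i = sqrt(mean_f |x_i(f) - mean_f x_i|^2) over selected atoms.

    Frames are iteratively superposed on their mean structure (2 rounds by
    default) before the fluctuations are measured; ``superpose=False`` skips
    the fitting for already-aligned synthetic trajectories.
    """
    idx = _selection_indices(traj.topology, selection)
    if not idx:
        raise StructureError("empty selection")
    frames = traj.frames
    if superpose:
        # fit on all heavy atoms (fitting on a small selection would absorb
        # a noticeable share of its own fluctuation), measure on `selection`
        fit_idx = _selection_indices(traj.topology, "heavy")
        frames = frames.copy()
        for _ in range(superposition_rounds):
            mean = frames[:, fit_idx, :].mean(axis=0)
            for f in range(frames.shape[0]):
                transform, _ = kabsch(frames[f][fit_idx], mean)
                frames[f] = transform.apply(frames[f])
    X = frames[:, idx, :]
    mean = X.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))
    residues = [(traj.topology.atoms[i].chain_id,
                 traj.topology.atoms[i].residue_number) for i in idx]
    # average atoms within a residue when the selection has several per residue
    order: list[tuple[str, int]] = []
    acc: dict[tuple[str, int], list[float]] = {}
    for r, v in zip(residues, fluct):
        if r not in acc:
            order.append(r)
            acc[r] = []
        acc[r].append(float(v))
    values = np.array([np.mean(acc[r]) for r in order])
    return RMSFProfile(order, values)


@dataclass
class TrajectoryClustering:
    frame_indices: list[int]       # original frame indices of strided frames
    partition: dict[int, int]      # frame index -> cluster id
    n_clusters: int
    representative: int            # frame index, medoid of the largest cluster


def cluster_trajectory(traj: Trajectory, stride: int = 10,
                       max_clusters: int = 10) -> TrajectoryClustering:
    """Cluster strided frames on heavy-atom RMSD; cut the dendrogram at
    min(max_clusters, Kelley optimum) and return the medoid of the largest
    cluster (ties to the lower frame index)."""
    if stride < 1 or stride >= traj.n_frames:
        raise ValueError(f"stride {stride} invalid for {traj.n_frames} frames")
    sel = _selection_indices(traj.topology, "heavy")
    frame_idx = list(range(0, traj.n_frames, stride))
    if len(frame_idx) < 2:
        raise ValueError("strided frame count must be >= 2")
    # align on the first strided frame so no-refit pairwise RMSD is meaningful
    ref = traj.frames[frame_idx[0]][sel]
    blocks = np.empty((len(frame_idx), len(sel), 3))
    for i, f in enumerate(frame_idx):
        transform, _ = kabsch(traj.frames[f][sel], ref)
        blocks[i] = transform.apply(traj.frames[f][sel])
    mat = pairwise_rmsd_matrix(blocks)
    labels = [str(f) for f in frame_idx]
    if max_clusters <= 1 or len(frame_idx) < 3 or mat.max() < 1e-6:
        assign = np.ones(len(frame_idx), dtype=int)
        k = 1
    else:
        matrix = RMSDMatrix(labels, mat)
        clustering = kelley_optimal_k(matrix)
        k = min(max_clusters, clustering.optimal_k)
        from scipy.cluster import hierarchy
        assign = hierarchy.fcluster(clustering.linkage_matrix, t=k,
                                    criterion="maxclust")
        k = len(np.unique(assign))
    sizes: dict[int, list[int]] = {}
    for i, cid in enumerate(assign):
        sizes.setdefault(int(cid), []).append(i)
    largest = min(sizes, key=lambda c: (-len(sizes[c]), min(sizes[c])))
    members = sizes[largest]
    sub = mat[np.ix_(members, members)]
    cost = (sub ** 2).sum(axis=1)
    medoid_local = min(range(len(members)),
                       key=lambda i: (cost[i], frame_idx[members[i]]))
    return TrajectoryClustering(
        frame_indices=frame_idx,
        partition={frame_idx[i]: int(c) for i, c in enumerate(assign)},
        n_clusters=int(k),
        representative=frame_idx[members[medoid_local]])
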