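"""Synthetic inputs for the whole pipeline: toy two-chain complexes with
planted interface contacts, multi-engine pose ensembles with a planted
consensus binding mode, and jittered trajectories.

Toy residues use a reduced representation (backbone N/CA/C/O plus C-beta and
one typed functional pseudo-atom) that satisfies every detection rule and
the surrogate energy without rotamer libraries. All generators are
bit-reproducible given (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .geometry import RigidTransform
from .pose_consensus import PoseEnsemble, PoseRecord
from .structure_io import Atom, Structure, StructureError
from .trajectory_metrics import Trajectory

__all__ = [
    "PlantedContact", "ToySpec", "EnsembleSpec", "DriftSpec",
    "build_toy_complex", "generate_pose_ensemble", "generate_trajectory",
]

CONTACT_KINDS = ("salt_bridge", "hbond", "hydrophobic_patch")

# (receptor residue name, functional atom, element), same for ligand side
_CONTACT_CHEMISTRY = {
    "salt_bridge": (("LYS", "NZ", "N"), ("GLU", "OE1", "O")),
    "hbond": (("SER", "OG", "O"), ("ASN", "OD1", "O")),
    "hydrophobic_patch": (("LEU", "CD1", "C"), ("LEU", "CD1", "C")),
}

_FILLER = ("LEU", "CD1", "C")  # apolar stub for non-contact residues

_CHAIN_GAP = 14.0      # backbone-to-backbone separation across the interface
_CA_SPACING = 3.8


@dataclass(frozen=True)
class PlantedContact:
    kind: str
    distance: float

    def __post_init__(self) -> None:
        if self.kind not in CONTACT_KINDS:
            raise ValueError(f"unknown contact kind {self.kind!r}")
        if not (0 < self.distance <= _CHAIN_GAP - 3.0):
            raise StructureError(
                f"contact distance {self.distance} infeasible for chain gap "
                f"{_CHAIN_GAP}")


@dataclass(frozen=True)
class ToySpec:
    receptor_length: int = 12
    ligand_length: int = 12
    planted_contacts: tuple[PlantedContact, ...] = (
        PlantedContact("salt_bridge", 3.0),
        PlantedContact("hbond", 3.0),
        PlantedContact("hydrophobic_patch", 4.0),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.receptor_length < 8 or self.ligand_length < 8:
            raise ValueError("chain lengths must be >= 8")
        if len(self.planted_contacts) * 3 > min(self.receptor_length,
                                                self.ligand_length):
            raise StructureError("too many contacts for the chain lengths")


@dataclass(frozen=True)
class GroundTruthContact:
    kind: str
    receptor_residue: tuple[str, int]
    ligand_residue: tuple[str, int]
    distance: float


def build_toy_complex(spec: ToySpec) -> tuple[Structure, list[GroundTruthContact]]:
    """Two parallel reduced chains (A = receptor, B = ligand) with each
    planted contact realized by functional pseudo-atoms meeting its target
    distance exactly; returns the complex and the ground-truth contact list.
    """
    rng = np.random.default_rng(spec.seed)
    # contact residues sit every 3rd position starting at the 2nd residue
    contact_slots = [2 + 3 * i for i in range(len(spec.planted_contacts))]

    atoms: list[Atom] = []
    serial = 1
    truth: list[GroundTruthContact] = []

    def add_chain(chain_id: str, length: int, y0: float, side: float,
                  contact_map: dict[int, tuple[tuple[str, str, str], float]]):
        nonlocal serial
        for i in range(1, length + 1):
            x = i * _CA_SPACING + rng.uniform(-0.02, 0.02)
            z = rng.uniform(-0.02, 0.02)
            res_info = contact_map.get(i)
            res_name, func_name, func_el = res_info[0] if res_info else _FILLER
            ca = np.array([x, y0, z])
            backbone = [
                ("N", "N", ca + np.array([-1.2, 0.6 * side, 0.3])),
                ("CA", "C", ca),
                ("C", "C", ca + np.array([1.2, 0.6 * side, -0.3])),
                ("O", "O", ca + np.array([1.4, 1.7 * side, -0.3])),
            ]
            # side chains point across the gap (receptor +y, ligand -y)
            cb = ca + np.array([0.0, -1.5 * side, 0.0])
            if res_info:
                func_y = res_info[1]
                func = np.array([x, func_y, 0.0])
            else:
                func = ca + np.array([0.0, -2.8 * side, 0.0])
            for aname, el, xyz in backbone + [("CB", "C", cb),
                                              (func_name, func_el, func)]:
                atoms.append(Atom(serial=serial, name=aname, element=el,
                                  residue_name=res_name, residue_number=i,
                                  chain_id=chain_id, coords=xyz))
                serial += 1

    rec_map: dict[int, tuple[tuple[str, str, str], float]] = {}
    lig_map: dict[int, tuple[tuple[str, str, str], float]] = {}
    for slot, contact in zip(contact_slots, spec.planted_contacts):
        rec_chem, lig_chem = _CONTACT_CHEMISTRY[contact.kind]
        y_rec = (_CHAIN_GAP - contact.distance) / 2.0
        rec_map[slot] = (rec_chem, y_rec)
        lig_map[slot] = (lig_chem, y_rec + contact.distance)
        truth.append(GroundTruthContact(
            kind=contact.kind, receptor_residue=("A", slot),
            ligand_residue=("B", slot), distance=contact.distance))

    add_chain("A", spec.receptor_length, 0.0, side=-1.0, contact_map=rec_map)
    add_chain("B", spec.ligand_length, _CHAIN_GAP, side=1.0, contact_map=lig_map)
    complex = Structure(atoms, id=f"toy-{spec.seed}",
                        chain_partition={"A": "receptor", "B": "ligand"})
    return complex, truth


# ---------------------------------------------------------------------------
# Pose ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnsembleSpec:
    n_engines: int = 9
    poses_per_engine: int = 5
    near_native_fraction: float = 0.6
    native_noise_sd: float = 1.0       # Angstrom; also sets rotation scale
    decoy_displacement: float = 15.0   # minimum ligand-centroid displacement
    rotation_sd_deg: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.near_native_fraction <= 1.0):
            raise ValueError("near_native_fraction must lie in [0, 1]")
        if self.decoy_displacement <= 3.0 * self.native_noise_sd:
            raise ValueError(
                "decoy_displacement must exceed 3 x native_noise_sd")
        if self.n_engines < 1 or self.poses_per_engine < 1:
            raise ValueError("need at least one engine and one pose")


def _random_rotation(rng: np.random.Generator, angle_sd_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = math.radians(rng.normal(0.0, angle_sd_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def generate_pose_ensemble(truth: Structure, spec: EnsembleSpec
                           ) -> tuple[PoseEnsemble, dict]:
    """Emulated multi-engine pose pool around a planted true binding mode.

    Near-native poses are small rigid perturbations of the true ligand pose
    (per-axis translation sd = native_noise_sd/sqrt(3), small rotation about
    the ligand centroid); decoys are randomly oriented placements whose
    ligand centroid is at least ``decoy_displacement`` from the true one and
    clash-free (no cross pair under 2 A). Labels follow X-m-n with X =
    ``engine01``.. and n = 1 (poses arrive pre-refined).
    """
    rng = np.random.default_rng(spec.seed)
    rec_idx = truth.role_indices("receptor")
    lig_idx = truth.role_indices("ligand")
    receptor = truth.subset(rec_idx, id=truth.id + "-receptor")
    ligand = truth.subset(lig_idx, id=truth.id + "-ligand")
    lig_xyz = ligand.coords
    lig_centroid = lig_xyz.mean(axis=0)
    rec_xyz = receptor.coords
    rec_centroid = rec_xyz.mean(axis=0)
    rec_radius = float(np.linalg.norm(rec_xyz - rec_centroid, axis=1).max())
    lig_radius = float(np.linalg.norm(lig_xyz - lig_centroid, axis=1).max())

    n_native = round(spec.near_native_fraction * spec.poses_per_engine)
    poses: list[PoseRecord] = []
    native_labels: list[str] = []
    for e in range(1, spec.n_engines + 1):
        engine = f"engine{e:02d}"
        for m in range(1, spec.poses_per_engine + 1):
            if m <= n_native:
                R = _random_rotation(rng, spec.rotation_sd_deg)
                t = rng.normal(0.0, spec.native_noise_sd / math.sqrt(3), size=3)
                coords = (lig_xyz - lig_centroid) @ R.T + lig_centroid + t
                native_labels.append(f"{engine}-{m}-1")
            else:
                coords = _place_decoy(rng, lig_xyz, lig_centroid, rec_xyz,
                                      rec_centroid, rec_radius, lig_radius,
                                      spec.decoy_displacement)
            poses.append(PoseRecord(coords, engine, m, 1))
    ensemble = PoseEnsemble(receptor, ligand, poses)
    truth_record = {
        "true_ligand_coords": lig_xyz,
        "near_native_labels": native_labels,
    }
    return ensemble, truth_record


def _place_decoy(rng, lig_xyz, lig_centroid, rec_xyz, rec_centroid,
                 rec_radius, lig_radius, min_displacement) -> np.ndarray:
    for _ in range(200):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        clearance = rec_radius + lig_radius + rng.uniform(2.0, 6.0)
        target = rec_centroid + u * clearance
        if np.linalg.norm(target - lig_centroid) < min_displacement:
            continue
        R = _random_rotation(rng, 180.0)
        coords = (lig_xyz - lig_centroid) @ R.T + target
        from scipy.spatial.distance import cdist
        if cdist(coords, rec_xyz).min() >= 2.0:
            return coords
    raise StructureError("could not place a clash-free decoy")


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DriftSpec:
    """Sinusoidal rigid displacement of a residue range (breathing motion)."""

    chain_id: str
    start_residue: int
    end_residue: int
    amplitude: float            # Angstrom
    period_frames: int
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)


def generate_trajectory(start: Structure, n_frames: int, jitter_sd: float,
                        drift: DriftSpec | None = None, seed: int = 0,
                        dt_ns: float = 1.0) -> Trajectory:
    """Isotropic Gaussian jitter about ``start``, with an optional sinusoidal
    displacement of a residue range to emulate an out/in helix motion."""
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    base = start.coords
    frames = base[None] + rng.normal(0.0, jitter_sd,
                                     size=(n_frames, base.shape[0], 3))
    if drift is not None:
        d = np.asarray(drift.direction, dtype=float)
        d /= np.linalg.norm(d)
        sel = np.array([drift.chain_id == a.chain_id
                        and drift.start_residue <= a.residue_number
                        <= drift.end_residue for a in start.atoms])
        phase = 2.0 * math.pi * np.arange(n_frames) / drift.period_frames
        offsets = drift.amplitude * np.sin(phase)
        frames[:, sel, :] += offsets[:, None, None] * d[None, None, :]
    return Trajectory(start, frames, dt_ns=dt_ns)
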