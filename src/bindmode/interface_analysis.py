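"""Typed interface-contact detection, occupancy over trajectories, distance
monitors and hot-region grouping.

Geometric criteria default to declared literature-style cutoffs (H-bond
donor-acceptor <= 3.5 A with a >= 120 deg donor-H-acceptor angle when
hydrogens are present; salt bridge <= 4.0 A between charged-group atoms;
ring-centroid pi-stacking <= 6.0 A; aromatic H-bond donor-to-centroid
<= 4.0 A) and are fully configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist, pdist

from . import chem
from .structure_io import Atom, Structure, StructureError

__all__ = [
    "InteractionCriteria", "InteractionRecord", "OccupancyEntry",
    "DistanceSeries", "HotRegion", "AtomSpec",
    "detect_interactions", "interface_residues", "monitor_distance",
    "interaction_occupancy", "hot_regions",
]

ResidueId = tuple[str, int, str]  # (chain, author number, residue name)


@dataclass(frozen=True)
class InteractionCriteria:
    hbond_distance: float = 3.5
    hbond_angle: float = 120.0           # donor-H-acceptor, degrees
    salt_bridge_distance: float = 4.0
    pi_centroid_distance: float = 6.0
    pi_parallel_max_angle: float = 30.0  # inter-plane, degrees
    pi_tshaped_min_angle: float = 60.0
    aromatic_hbond_distance: float = 4.0
    interface_cutoff: float = 4.5


@dataclass(frozen=True)
class InteractionRecord:
    """One typed cross-interface contact between two residues."""

    type: str  # hbond | salt_bridge | pi_stacking | aromatic_hbond
    receptor_residue: ResidueId
    ligand_residue: ResidueId
    distance: float
    atoms: tuple[str, str]

    @property
    def key(self) -> tuple:
        return (self.type, self.receptor_residue[:2], self.ligand_residue[:2])


@dataclass
class OccupancyEntry:
    type: str
    receptor_residue: ResidueId
    ligand_residue: ResidueId
    occupancy: float
    mean_distance: float
    sd_distance: float
    stable: bool


@dataclass
class DistanceSeries:
    pair: str
    distances: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.distances))

    @property
    def sd(self) -> float:
        return float(np.std(self.distances, ddof=0))


@dataclass
class HotRegion:
    region_id: int
    members: list[tuple[str, int]]
    center: np.ndarray


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _residue_id(a: Atom) -> ResidueId:
    return (a.chain_id, a.residue_number, a.residue_name)


def _attached_hydrogens(structure: Structure, donor_idx: int) -> list[int]:
    donor = structure.atoms[donor_idx]
    out = []
    for i, a in enumerate(structure.atoms):
        if (not a.is_heavy and a.residue_key == donor.residue_key
                and np.linalg.norm(a.coords - donor.coords) <= 1.3):
            out.append(i)
    return out


def _hbond_geometry_ok(structure: Structure, donor_idx: int,
                       acceptor_coords: np.ndarray,
                       criteria: InteractionCriteria) -> bool:
    """Angle test using attached hydrogens; distance-only if none present."""
    hs = _attached_hydrogens(structure, donor_idx)
    if not hs:
        return True
    d = structure.atoms[donor_idx].coords
    for hi in hs:
        h = structure.atoms[hi].coords
        v1 = d - h
        v2 = acceptor_coords - h
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
        if ang >= criteria.hbond_angle:
            return True
    return False


def _rings(structure: Structure, indices: list[int]
           ) -> list[tuple[ResidueId, np.ndarray, np.ndarray, str]]:
    """(residue id, centroid, unit normal, ring tag) for complete rings."""
    by_res: dict[tuple, dict[str, int]] = {}
    for i in indices:
        a = structure.atoms[i]
        by_res.setdefault(a.residue_key, {})[a.name] = i
    out = []
    for res_key, names in by_res.items():
        first = structure.atoms[next(iter(names.values()))]
        for ring_no, ring_names in enumerate(
                chem.AROMATIC_RINGS.get(first.residue_name, [])):
            if not all(n in names for n in ring_names):
                continue
            pts = np.array([structure.atoms[names[n]].coords
                            for n in ring_names])
            centroid = pts.mean(axis=0)
            _, _, vt = np.linalg.svd(pts - centroid)
            normal = vt[2] / np.linalg.norm(vt[2])
            out.append((_residue_id(first), centroid, normal,
                        f"ring{ring_no}"))
    return out


def detect_interactions(complex: Structure,
                        criteria: InteractionCriteria | None = None
                        ) -> list[InteractionRecord]:
    """Detect typed noncovalent contacts across the receptor/ligand interface.

    Atom-level hits are collapsed to one record per (type, residue pair)
    keeping the closest defining distance; output is sorted by receptor
    residue, ligand residue, then type.
    """
    criteria = criteria or InteractionCriteria()
    rec_idx = complex.role_indices("receptor")
    lig_idx = complex.role_indices("ligand")
    if not rec_idx or not lig_idx:
        raise StructureError("complex needs both receptor and ligand atoms")

    best: dict[tuple, InteractionRecord] = {}

    def offer(rec: InteractionRecord) -> None:
        k = rec.key
        if k not in best or rec.distance < best[k].distance:
            best[k] = rec

    atoms = complex.atoms
    rec_heavy = [i for i in rec_idx if atoms[i].is_heavy]
    lig_heavy = [i for i in lig_idx if atoms[i].is_heavy]
    max_cut = max(criteria.hbond_distance, criteria.salt_bridge_distance)
    D = cdist(np.array([atoms[i].coords for i in rec_heavy]),
              np.array([atoms[j].coords for j in lig_heavy]))

    def pair_scan(i: int, j: int, d: float, oriented: bool):
        """oriented=True means atom i is on the receptor side."""
        ai, aj = atoms[i], atoms[j]
        rres, lres = (_residue_id(ai), _residue_id(aj)) if oriented \
            else (_residue_id(aj), _residue_id(ai))
        anames = (ai.name, aj.name) if oriented else (aj.name, ai.name)
        # hydrogen bond: i donates to j
        if (d <= criteria.hbond_distance and chem.is_donor(ai)
                and chem.is_acceptor(aj)
                and _hbond_geometry_ok(complex, i, aj.coords, criteria)):
            offer(InteractionRecord("hbond", rres, lres, d, anames))
        # salt bridge: i cationic, j anionic
        if (d <= criteria.salt_bridge_distance
                and chem.is_cation(ai, complex) and chem.is_anion(aj)):
            offer(InteractionRecord("salt_bridge", rres, lres, d, anames))

    for r, c in np.argwhere(D <= max_cut):
        i, j = rec_heavy[r], lig_heavy[c]
        d = float(D[r, c])
        pair_scan(i, j, d, oriented=True)
        pair_scan(j, i, d, oriented=False)

    # pi-stacking and aromatic hydrogen bonds
    rec_rings = _rings(complex, rec_idx)
    lig_rings = _rings(complex, lig_idx)
    for rres, c1, n1, t1 in rec_rings:
        for lres, c2, n2, t2 in lig_rings:
            d = float(np.linalg.norm(c1 - c2))
            if d > criteria.pi_centroid_distance:
                continue
            ang = math.degrees(math.acos(np.clip(abs(np.dot(n1, n2)), 0, 1)))
            if (ang <= criteria.pi_parallel_max_angle
                    or ang >= criteria.pi_tshaped_min_angle):
                offer(InteractionRecord("pi_stacking", rres, lres, d, (t1, t2)))

    def aromatic_hb(rings, donor_side, rings_are_receptor: bool):
        for res_ring, centroid, _, tag in rings:
            for i in donor_side:
                a = complex.atoms[i]
                if not (a.is_heavy and chem.is_donor(a)):
                    continue
                d = float(np.linalg.norm(a.coords - centroid))
                if d <= criteria.aromatic_hbond_distance:
                    if rings_are_receptor:
                        offer(InteractionRecord("aromatic_hbond", res_ring,
                                                _residue_id(a), d, (tag, a.name)))
                    else:
                        offer(InteractionRecord("aromatic_hbond", _residue_id(a),
                                                res_ring, d, (a.name, tag)))

    aromatic_hb(rec_rings, lig_idx, rings_are_receptor=True)
    aromatic_hb(lig_rings, rec_idx, rings_are_receptor=False)

    return sorted(best.values(),
                  key=lambda r: (r.receptor_residue, r.ligand_residue, r.type))


def interface_residues(complex: Structure, cutoff: float = 4.5
                       ) -> dict[str, set[tuple[str, int]]]:
    """Residues whose minimum heavy-atom cross distance is <= cutoff."""
    rec_idx = complex.role_indices("receptor")
    lig_idx = complex.role_indices("ligand")
    if not rec_idx or not lig_idx:
        raise StructureError("complex needs both receptor and ligand atoms")
    atoms = complex.atoms
    rec_heavy = [i for i in rec_idx if atoms[i].is_heavy]
    lig_heavy = [i for i in lig_idx if atoms[i].is_heavy]
    D = cdist(np.array([atoms[i].coords for i in rec_heavy]),
              np.array([atoms[i].coords for i in lig_heavy]))
    hit = D <= cutoff
    out = {"receptor": set(), "ligand": set()}
    for r, i in enumerate(rec_heavy):
        if hit[r].any():
            out["receptor"].add((atoms[i].chain_id, atoms[i].residue_number))
    for c, j in enumerate(lig_heavy):
        if hit[:, c].any():
            out["ligand"].add((atoms[j].chain_id, atoms[j].residue_number))
    return out


# ---------------------------------------------------------------------------
# Trajectory monitors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomSpec:
    """Atom or atom-group target, e.g. ``A:1643:ND2`` or ``GTP:gamma-phosphate``."""

    text: str

    def resolve(self, s: Structure) -> list[int]:
        parts = self.text.split(":")
        if len(parts) == 3:
            c, n, an = parts
            idx = [i for i, a in enumerate(s.atoms)
                   if a.chain_id == c and a.residue_number == int(n)
                   and a.name == an]
        elif len(parts) == 2:
            resname, group = parts
            if group == "gamma-phosphate":
                names = chem.GAMMA_PHOSPHATE
            else:
                names = {group}
            idx = [i for i, a in enumerate(s.atoms)
                   if a.residue_name == resname and a.name in names]
        else:
            raise StructureError(f"cannot parse atom spec {self.text!r}")
        if not idx:
            raise StructureError(f"atom spec {self.text!r} matches no atoms")
        return idx


def monitor_distance(topology: Structure, frames: np.ndarray,
                     spec_a: AtomSpec | str, spec_b: AtomSpec | str
                     ) -> DistanceSeries:
    """Per-frame distance between an atom and an atom or group.

    For a group target the distance is to the nearest group atom each frame.
    """
    if isinstance(spec_a, str):
        spec_a = AtomSpec(spec_a)
    if isinstance(spec_b, str):
        spec_b = AtomSpec(spec_b)
    ia = spec_a.resolve(topology)
    ib = spec_b.resolve(topology)
    frames = np.asarray(frames, dtype=float)
    dists = np.empty(frames.shape[0])
    for f in range(frames.shape[0]):
        D = cdist(frames[f, ia], frames[f, ib])
        dists[f] = D.min()
    return DistanceSeries(f"{spec_a.text}--{spec_b.text}", dists)


def interaction_occupancy(topology: Structure, frames: np.ndarray,
                          criteria: InteractionCriteria | None = None
                          ) -> list[OccupancyEntry]:
    """Per-frame interaction detection summarized as residue-pair occupancies.

    An interaction is ``stable`` when present in at least 50% of frames
    (boundary inclusive). Atom-level variants collapse to the residue pair
    and type; the reported distance statistics run over frames where the
    interaction is present.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.shape[0] < 2:
        raise ValueError("occupancy needs at least 2 frames")
    counts: dict[tuple, list[float]] = {}
    ids: dict[tuple, tuple[ResidueId, ResidueId, str]] = {}
    for f in range(frames.shape[0]):
        snap = topology.with_coords(frames[f])
        for rec in detect_interactions(snap, criteria):
            counts.setdefault(rec.key, []).append(rec.distance)
            ids[rec.key] = (rec.receptor_residue, rec.ligand_residue, rec.type)
    n = frames.shape[0]
    entries = []
    for key in sorted(counts, key=lambda k: (ids[k][0], ids[k][1], ids[k][2])):
        dlist = np.array(counts[key])
        occ = len(dlist) / n
        rres, lres, typ = ids[key]
        entries.append(OccupancyEntry(
            type=typ, receptor_residue=rres, ligand_residue=lres,
            occupancy=occ, mean_distance=float(dlist.mean()),
            sd_distance=float(dlist.std(ddof=0)), stable=occ >= 0.5))
    return entries


# ---------------------------------------------------------------------------
# Hot regions
# ---------------------------------------------------------------------------

def hot_regions(hotspots: Iterable[tuple[str, int]], structure: Structure,
                linkage_cutoff: float = 12.0) -> list[HotRegion]:
    """Group hotspot residues into spatial regions by single-linkage on
    C-alpha distance; regions are sorted by decreasing size."""
    spots = sorted(set((str(c), int(n)) for c, n in hotspots))
    if not spots:
        raise ValueError("need at least one hotspot residue")
    ca = {}
    for a in structure.atoms:
        if a.name == "CA":
            ca[(a.chain_id, a.residue_number)] = a.coords
    missing = [s for s in spots if s not in ca]
    if missing:
        raise StructureError(f"hotspot residues lack CA atoms: {missing}")
    pts = np.array([ca[s] for s in spots])
    if len(spots) == 1:
        assign = np.array([1])
    else:
        Z = hierarchy.linkage(pdist(pts), method="single")
        assign = hierarchy.fcluster(Z, t=linkage_cutoff, criterion="distance")
    groups: dict[int, list[int]] = {}
    for i, cid in enumerate(assign):
        groups.setdefault(int(cid), []).append(i)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), spots[g[0]]))
    return [HotRegion(region_id=r + 1,
                      members=[spots[i] for i in g],
                      center=pts[g].mean(axis=0))
            for r, g in enumerate(ordered)]
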