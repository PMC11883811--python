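"""Surrogate interface binding-energy model, per-frame trajectory averaging,
alanine scanning and multi-scorer hotspot consensus.

The energy function is a declared surrogate: 12-6 Lennard-Jones with
element-class parameters, Coulomb electrostatics between formal-charge
centers under a distance-dependent dielectric eps(r) = 4r, a fixed reward
per detected cross-interface hydrogen bond, and a fixed reward per apolar
heavy-atom contact. Binding energy follows the end-point convention
dG_bind = G_complex - G_receptor - G_ligand with the separated partners
keeping the complex geometry (single-trajectory convention), so dG_bind
reduces exactly to the sum of cross-interface terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from . import chem
from .interface_analysis import InteractionCriteria, detect_interactions
from .structure_io import Structure, StructureError
from .trajectory_metrics import Trajectory

__all__ = [
    "EnergyModel", "EnergyDecomposition", "TrajectoryEnergySummary",
    "HotspotTable", "ConsensusRow",
    "interface_energy", "trajectory_binding_energy", "alanine_scan",
    "hotspot_consensus", "mutate_to_alanine",
]

# (epsilon kcal/mol, rmin/2 Angstrom) per element class
DEFAULT_LJ = {
    "C": (0.1094, 1.9080),
    "N": (0.1700, 1.8240),
    "O": (0.2100, 1.6612),
    "S": (0.2500, 2.0000),
    "P": (0.2000, 2.1000),
    "H": (0.0157, 0.6000),
    "MG": (0.8750, 0.7926),
}

COULOMB_CONSTANT = 332.0636  # kcal*A/(mol*e^2)


@dataclass(frozen=True)
class EnergyModel:
    lj_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LJ))
    lj_cutoff: float = 10.0
    dielectric_factor: float = 4.0   # eps(r) = factor * r
    elec_cutoff: float = 12.0
    hbond_reward: float = -1.0       # kcal/mol per detected cross H-bond
    lipo_reward: float = -0.1        # kcal/mol per apolar cross contact
    lipo_cutoff: float = 4.5
    criteria: InteractionCriteria = field(default_factory=InteractionCriteria)

    def __post_init__(self) -> None:
        if self.hbond_reward > 0 or self.lipo_reward > 0:
            raise ValueError("rewards must be <= 0")
        for c in (self.lj_cutoff, self.elec_cutoff, self.lipo_cutoff):
            if c <= 0:
                raise ValueError("cutoffs must be positive")


@dataclass
class EnergyDecomposition:
    G_complex: float
    G_receptor: float
    G_ligand: float
    dG_bind: float
    dG_vdW: float
    dG_elec: float
    dG_Hbond: float
    dG_Lipo: float

    def components(self) -> dict[str, float]:
        return {"dG_vdW": self.dG_vdW, "dG_elec": self.dG_elec,
                "dG_Hbond": self.dG_Hbond, "dG_Lipo": self.dG_Lipo}


@dataclass
class TrajectoryEnergySummary:
    frame_indices: list[int]
    per_frame: list[EnergyDecomposition]
    mean_dG: float
    se_dG: float       # sd / sqrt(n), primary error estimate
    sd_dG: float
    component_means: dict[str, float]
    component_se: dict[str, float]


def _element_params(model: EnergyModel, element: str) -> tuple[float, float]:
    el = element.upper()
    try:
        return model.lj_params[el]
    except KeyError:
        raise StructureError(f"unparameterized element {el!r}") from None


def _pair_energy(s: Structure, idx_a: Sequence[int], idx_b: Sequence[int],
                 model: EnergyModel, exclude_near: bool
                 ) -> tuple[float, float, float]:
    """(vdW, elec, lipo) summed over atom pairs between two index groups.

    ``exclude_near`` skips same-residue and sequence-adjacent pairs (used
    within one partner, where bonded contacts would dominate the LJ term).
    """
    atoms = s.atoms
    A = np.array([atoms[i].coords for i in idx_a])
    B = np.array([atoms[j].coords for j in idx_b])
    D = cdist(A, B)
    eps_a = np.empty(len(idx_a)); rmin_a = np.empty(len(idx_a))
    for k, i in enumerate(idx_a):
        eps_a[k], rmin_a[k] = _element_params(model, atoms[i].element)
    eps_b = np.empty(len(idx_b)); rmin_b = np.empty(len(idx_b))
    for k, j in enumerate(idx_b):
        eps_b[k], rmin_b[k] = _element_params(model, atoms[j].element)
    q_a = np.array([chem.formal_charge(atoms[i]) for i in idx_a])
    q_b = np.array([chem.formal_charge(atoms[j]) for j in idx_b])
    apolar_a = np.array([chem.is_apolar(atoms[i]) and atoms[i].is_heavy
                         for i in idx_a])
    apolar_b = np.array([chem.is_apolar(atoms[j]) and atoms[j].is_heavy
                         for j in idx_b])

    mask = np.ones(D.shape, dtype=bool)
    if exclude_near:
        for k, i in enumerate(idx_a):
            ai = atoms[i]
            for l, j in enumerate(idx_b):
                aj = atoms[j]
                if (ai.chain_id == aj.chain_id
                        and abs(ai.residue_number - aj.residue_number) <= 1):
                    mask[k, l] = False
    mask &= D > 1e-6  # drop self pairs when idx_a and idx_b overlap

    with np.errstate(divide="ignore", invalid="ignore"):
        # vdW
        eps_ij = np.sqrt(np.outer(eps_a, eps_b))
        rmin_ij = rmin_a[:, None] + rmin_b[None, :]
        sel = mask & (D <= model.lj_cutoff)
        ratio = np.where(sel, rmin_ij / np.where(D > 0, D, 1.0), 0.0)
        vdw = float(np.sum(eps_ij[sel] * (ratio[sel] ** 12 - 2.0 * ratio[sel] ** 6)))
        # electrostatics, eps(r) = factor * r  ->  E = k q q / (factor r^2)
        qq = np.outer(q_a, q_b)
        esel = mask & (D <= model.elec_cutoff) & (qq != 0)
        elec = float(np.sum(COULOMB_CONSTANT * qq[esel]
                            / (model.dielectric_factor * D[esel] ** 2)))
        # lipophilic contacts
        lsel = mask & (D <= model.lipo_cutoff) & np.outer(apolar_a, apolar_b)
        lipo = float(model.lipo_reward * np.count_nonzero(lsel))
    return vdw, elec, lipo


def interface_energy(complex: Structure,
                     model: EnergyModel | None = None) -> EnergyDecomposition:
    """End-point binding energy with the complex geometry reused for the
    separated partners, so all intra-partner terms cancel exactly and
    dG_bind equals the cross-interface sum (and the component sum)."""
    model = model or EnergyModel()
    rec = complex.role_indices("receptor")
    lig = complex.role_indices("ligand")
    if not rec or not lig:
        raise StructureError("complex needs both receptor and ligand atoms")
    cross_vdw, cross_elec, cross_lipo = _pair_energy(
        complex, rec, lig, model, exclude_near=False)
    n_hbonds = sum(1 for r in detect_interactions(complex, model.criteria)
                   if r.type in ("hbond", "aromatic_hbond"))
    dG_hbond = model.hbond_reward * n_hbonds
    # intra terms are shared between complex and separated partner
    intra_rec = sum(_pair_energy(complex, rec, rec, model, exclude_near=True)) / 2.0
    intra_lig = sum(_pair_energy(complex, lig, lig, model, exclude_near=True)) / 2.0
    dG = cross_vdw + cross_elec + dG_hbond + cross_lipo
    return EnergyDecomposition(
        G_complex=intra_rec + intra_lig + dG,
        G_receptor=intra_rec, G_ligand=intra_lig, dG_bind=dG,
        dG_vdW=cross_vdw, dG_elec=cross_elec, dG_Hbond=dG_hbond,
        dG_Lipo=cross_lipo)


def trajectory_binding_energy(traj: Trajectory, model: EnergyModel | None = None,
                              stride_ns: float = 2.0) -> TrajectoryEnergySummary:
    """Binding energy on frames extracted every ``stride_ns``; mean with
    standard error sd/sqrt(n) (sd also reported)."""
    model = model or EnergyModel()
    stride = max(1, int(round(stride_ns / traj.dt_ns)))
    span = (traj.n_frames - 1) * traj.dt_ns
    if stride_ns > span:
        raise ValueError(f"stride {stride_ns} ns exceeds trajectory span {span} ns")
    frame_idx = list(range(0, traj.n_frames, stride))
    if len(frame_idx) < 2:
        raise ValueError("need at least 2 strided frames")
    per_frame = [interface_energy(traj.frame_structure(f), model)
                 for f in frame_idx]
    dgs = np.array([e.dG_bind for e in per_frame])
    n = len(dgs)
    comp_means, comp_se = {}, {}
    for key in ("dG_vdW", "dG_elec", "dG_Hbond", "dG_Lipo"):
        vals = np.array([getattr(e, key) for e in per_frame])
        comp_means[key] = float(vals.mean())
        comp_se[key] = float(vals.std(ddof=0) / np.sqrt(n))
    return TrajectoryEnergySummary(
        frame_indices=frame_idx, per_frame=per_frame,
        mean_dG=float(dgs.mean()),
        se_dG=float(dgs.std(ddof=0) / np.sqrt(n)),
        sd_dG=float(dgs.std(ddof=0)),
        component_means=comp_means, component_se=comp_se)


# ---------------------------------------------------------------------------
# Alanine scanning
# ---------------------------------------------------------------------------

_BACKBONE_KEEP = {"N", "CA", "C", "O", "OXT", "CB",
                  "H", "HA", "H1", "H2", "H3"}


def mutate_to_alanine(complex: Structure, residue: tuple[str, int]) -> Structure:
    """Side-chain truncation to C-beta; glycine is returned unchanged."""
    c, n = str(residue[0]), int(residue[1])
    res_atoms = [a for a in complex.atoms
                 if a.chain_id == c and a.residue_number == n]
    if not res_atoms:
        raise StructureError(f"residue {c}:{n} not found")
    res_name = res_atoms[0].residue_name
    if res_name not in chem.STANDARD_AA:
        raise StructureError(f"residue {c}:{n} ({res_name}) is not a standard "
                             f"amino acid")
    if res_name in ("GLY", "ALA"):
        return complex
    keep = [i for i, a in enumerate(complex.atoms)
            if not (a.chain_id == c and a.residue_number == n
                    and a.name not in _BACKBONE_KEEP)]
    return complex.subset(keep)


@dataclass
class HotspotTable:
    scorer: str
    ddG: dict[tuple[str, int], float]            # residue -> ddG kcal/mol
    is_hotspot: dict[tuple[str, int], bool]
    threshold: float
    flagged_glycines: set[tuple[str, int]] = field(default_factory=set)

    def ranking(self) -> list[tuple[str, int]]:
        """Residues by decreasing ddG; ties broken by (chain, number)."""
        return sorted(self.ddG, key=lambda r: (-self.ddG[r], r))


def alanine_scan(complex: Structure, residues: Iterable[tuple[str, int]],
                 model: EnergyModel | None = None,
                 hotspot_threshold: float = 1.0,
                 scorer: str = "truncation") -> HotspotTable:
    """Computational alanine scan by side-chain truncation.

    ddG = dG_bind(mutant) - dG_bind(wild type); positive means binding is
    weakened. Alanines give exactly 0; glycines are not mutated and are
    flagged. ``is_hotspot`` at ddG >= threshold (default 1.0 kcal/mol).
    """
    model = model or EnergyModel()
    wt = interface_energy(complex, model).dG_bind
    ddG: dict[tuple[str, int], float] = {}
    hotspot: dict[tuple[str, int], bool] = {}
    glycines: set[tuple[str, int]] = set()
    for residue in residues:
        key = (str(residue[0]), int(residue[1]))
        mutant = mutate_to_alanine(complex, key)
        if mutant is complex:
            res_name = next(a.residue_name for a in complex.atoms
                            if (a.chain_id, a.residue_number) == key)
            if res_name == "GLY":
                glycines.add(key)
            ddG[key] = 0.0
        else:
            ddG[key] = interface_energy(mutant, model).dG_bind - wt
        hotspot[key] = ddG[key] >= hotspot_threshold
    return HotspotTable(scorer=scorer, ddG=ddG, is_hotspot=hotspot,
                        threshold=hotspot_threshold, flagged_glycines=glycines)


@dataclass
class ConsensusRow:
    residue: tuple[str, int]
    borda_score: int           # sum of per-table ranks; lower binds tighter
    consensus_rank: int
    is_hotspot: bool           # hotspot in at least half the tables
    per_scorer_ddG: dict[str, float]


def hotspot_consensus(tables: Sequence[HotspotTable]) -> list[ConsensusRow]:
    """Rank-sum (Borda) consensus over >= 2 hotspot tables sharing residues."""
    if len(tables) < 2:
        raise ValueError("need at least 2 tables for a consensus")
    residues = set(tables[0].ddG)
    for t in tables[1:]:
        if set(t.ddG) != residues:
            raise ValueError("hotspot tables do not share the same residue set")
    borda = {r: 0 for r in residues}
    for t in tables:
        for rank, r in enumerate(t.ranking(), start=1):
            borda[r] += rank
    hot_votes = {r: sum(1 for t in tables if t.is_hotspot[r]) for r in residues}
    ordered = sorted(residues, key=lambda r: (borda[r], r))
    return [ConsensusRow(
        residue=r, borda_score=borda[r], consensus_rank=i + 1,
        is_hotspot=hot_votes[r] * 2 >= len(tables),
        per_scorer_ddG={t.scorer: t.ddG[r] for t in tables})
        for i, r in enumerate(ordered)]
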