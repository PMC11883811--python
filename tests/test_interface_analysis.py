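import math

import numpy as np
import pytest

from bindmode import chem
from bindmode import synthetic_data as sd
from bindmode.interface_analysis import (AtomSpec, InteractionCriteria,
                                         detect_interactions, hot_regions,
                                         interaction_occupancy,
                                         interface_residues, monitor_distance)
from bindmode.structure_io import Atom, Structure, StructureError

from conftest import make_simple_structure


def _complex_from_atoms(specs):
    """specs: (name, element, resname, resnum, chain, xyz)."""
    atoms = [Atom(i + 1, n, el, rn, num, c, np.asarray(xyz, dtype=float))
             for i, (n, el, rn, num, c, xyz) in enumerate(specs)]
    return Structure(atoms, chain_partition={"A": "receptor", "B": "ligand"})


def test_salt_bridge_and_hbond_detected():
    s = _complex_from_atoms([
        ("NZ", "N", "LYS", 1, "A", (0, 0, 0)),
        ("OE1", "O", "GLU", 1, "B", (3.0, 0, 0)),
    ])
    types = {r.type for r in detect_interactions(s)}
    assert types == {"salt_bridge", "hbond"}
    sb = next(r for r in detect_interactions(s) if r.type == "salt_bridge")
    assert sb.distance == pytest.approx(3.0)
    assert sb.atoms == ("NZ", "OE1")


def test_distant_partners_give_empty_list():
    s = _complex_from_atoms([
        ("NZ", "N", "LYS", 1, "A", (0, 0, 0)),
        ("OE1", "O", "GLU", 1, "B", (20.0, 0, 0)),
    ])
    assert detect_interactions(s) == []


def test_hbond_angle_rejects_bad_geometry():
    # donor H points away from the acceptor -> angle ~0 deg, rejected
    s = _complex_from_atoms([
        ("OG", "O", "SER", 1, "A", (0, 0, 0)),
        ("HG", "H", "SER", 1, "A", (0.95, 0, 0)),
        ("OD1", "O", "ASN", 1, "B", (3.2, 0, 0)),
    ])
    good = [r for r in detect_interactions(s) if r.type == "hbond"]
    assert good  # H between donor and acceptor: angle ~180 deg
    s2 = _complex_from_atoms([
        ("OG", "O", "SER", 1, "A", (0, 0, 0)),
        ("HG", "H", "SER", 1, "A", (-0.95, 0, 0)),
        ("OD1", "O", "ASN", 1, "B", (3.2, 0, 0)),
    ])
    assert [r for r in detect_interactions(s2) if r.type == "hbond"] == []


def _phe_ring(resnum, chain, center, normal_axis="z"):
    center = np.asarray(center, dtype=float)
    ring_names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
    out = []
    for i, name in enumerate(ring_names):
        ang = 2 * math.pi * i / 6
        if normal_axis == "z":
            offset = np.array([1.4 * math.cos(ang), 1.4 * math.sin(ang), 0.0])
        else:  # normal along x
            offset = np.array([0.0, 1.4 * math.cos(ang), 1.4 * math.sin(ang)])
        out.append((name, "C", "PHE", resnum, chain, center + offset))
    return out


def test_pi_stacking_parallel_at_table_distance():
    # 5.69 A centroid separation, parallel rings -> detected
    s = _complex_from_atoms(_phe_ring(1, "A", (0, 0, 0))
                            + _phe_ring(1, "B", (0, 0, 5.69)))
    recs = [r for r in detect_interactions(s) if r.type == "pi_stacking"]
    assert len(recs) == 1
    assert recs[0].distance == pytest.approx(5.69, abs=1e-9)


def test_pi_stacking_tshaped_and_cutoff():
    s = _complex_from_atoms(_phe_ring(1, "A", (0, 0, 0))
                            + _phe_ring(1, "B", (0, 0, 5.0),
                                        normal_axis="x"))
    assert any(r.type == "pi_stacking" for r in detect_interactions(s))
    far = _complex_from_atoms(_phe_ring(1, "A", (0, 0, 0))
                              + _phe_ring(1, "B", (0, 0, 6.5)))
    assert not any(r.type == "pi_stacking" for r in detect_interactions(far))


def test_aromatic_hbond():
    s = _complex_from_atoms(_phe_ring(1, "A", (0, 0, 0))
                            + [("NZ", "N", "LYS", 1, "B", (0, 0, 3.5))])
    recs = [r for r in detect_interactions(s) if r.type == "aromatic_hbond"]
    assert len(recs) == 1
    assert recs[0].distance == pytest.approx(3.5, abs=1e-9)


def test_histidine_needs_protons_for_salt_bridge():
    base = [("NE2", "N", "HIS", 1, "A", (0, 0, 0)),
            ("OE1", "O", "GLU", 1, "B", (3.5, 0, 0))]
    s = _complex_from_atoms(base)
    assert not any(r.type == "salt_bridge" for r in detect_interactions(s))
    s2 = _complex_from_atoms(base + [
        ("HD1", "H", "HIS", 1, "A", (-1.0, 1.0, 0)),
        ("HE2", "H", "HIS", 1, "A", (0.4, -0.9, 0))])
    assert any(r.type == "salt_bridge" for r in detect_interactions(s2))


def test_detection_matches_bruteforce_oracle(toy_complex):
    records = detect_interactions(toy_complex)
    crit = InteractionCriteria()
    expected = set()
    atoms = toy_complex.atoms
    rec = toy_complex.role_indices("receptor")
    lig = toy_complex.role_indices("ligand")
    for i in rec:
        for j in lig:
            a, b = atoms[i], atoms[j]
            if not (a.is_heavy and b.is_heavy):
                continue
            d = float(np.linalg.norm(a.coords - b.coords))
            for x, y in ((a, b), (b, a)):
                if (d <= crit.hbond_distance and chem.is_donor(x)
                        and chem.is_acceptor(y)):
                    expected.add(("hbond", a.residue_key[:2], b.residue_key[:2]))
                if (d <= crit.salt_bridge_distance
                        and chem.is_cation(x, toy_complex) and chem.is_anion(y)):
                    expected.add(("salt_bridge", a.residue_key[:2],
                                  b.residue_key[:2]))
    got = {(r.type, (r.receptor_residue[0], r.receptor_residue[1]),
            (r.ligand_residue[0], r.ligand_residue[1])) for r in records}
    assert got == expected


def test_symmetry_under_role_swap(toy_complex):
    forward = detect_interactions(toy_complex)
    swapped = toy_complex.copy()
    swapped.chain_partition = {"A": "ligand", "B": "receptor"}
    backward = detect_interactions(swapped)
    fw = {(r.type, r.receptor_residue, r.ligand_residue) for r in forward}
    bw = {(r.type, r.ligand_residue, r.receptor_residue) for r in backward}
    assert fw == bw


def test_planted_salt_bridge_always_found_and_lost_on_separation(toy):
    complex, truth = toy
    sb = next(t for t in truth if t.kind == "salt_bridge")
    recs = [r for r in detect_interactions(complex) if r.type == "salt_bridge"]
    assert [(r.receptor_residue[:2], r.ligand_residue[:2]) for r in recs] == \
        [(sb.receptor_residue, sb.ligand_residue)]
    # rigid 10 A separation of the ligand chain removes it
    coords = complex.coords
    lig_idx = complex.role_indices("ligand")
    coords[lig_idx] += np.array([0.0, 10.0, 0.0])
    apart = complex.with_coords(coords)
    assert not any(r.type == "salt_bridge"
                   for r in detect_interactions(apart))


def test_missing_roles_error(toy_complex):
    bare = toy_complex.copy()
    bare.chain_partition = {}
    with pytest.raises(StructureError):
        detect_interactions(bare)


# ---------------------------------------------------------------------------
# interface_residues
# ---------------------------------------------------------------------------

def test_interface_residue_inclusion():
    s = _complex_from_atoms([
        ("CA", "C", "ALA", 1, "A", (0, 0, 0)),
        ("CA", "C", "ALA", 1, "B", (4.0, 0, 0)),
    ])
    out = interface_residues(s, cutoff=4.5)
    assert out == {"receptor": {("A", 1)}, "ligand": {("B", 1)}}
    assert interface_residues(s, cutoff=0.1) == {"receptor": set(),
                                                 "ligand": set()}


def test_interface_residues_match_bruteforce(toy_complex):
    cutoff = 4.5
    out = interface_residues(toy_complex, cutoff)
    atoms = toy_complex.atoms
    rec = [a for i, a in enumerate(atoms)
           if i in toy_complex.role_indices("receptor") and a.is_heavy]
    lig = [a for i, a in enumerate(atoms)
           if i in toy_complex.role_indices("ligand") and a.is_heavy]
    exp_r = {(a.chain_id, a.residue_number) for a in rec
             if min(np.linalg.norm(a.coords - b.coords) for b in lig) <= cutoff}
    exp_l = {(b.chain_id, b.residue_number) for b in lig
             if min(np.linalg.norm(a.coords - b.coords) for a in rec) <= cutoff}
    assert out == {"receptor": exp_r, "ligand": exp_l}


# ---------------------------------------------------------------------------
# monitor_distance
# ---------------------------------------------------------------------------

def _pair_trajectory(distances):
    topo = _complex_from_atoms([
        ("ND2", "N", "ASN", 1643, "A", (0, 0, 0)),
        ("PG", "P", "GTP", 900, "B", (7, 0, 0)),
        ("O1G", "O", "GTP", 900, "B", (8, 1, 0)),
    ])
    frames = []
    for d in distances:
        frames.append(np.array([[0, 0, 0], [d, 0, 0], [d + 1, 1, 0.0]]))
    return topo, np.stack(frames)


def test_constant_distance():
    topo, frames = _pair_trajectory([7.0] * 5)
    s = monitor_distance(topo, frames, "A:1643:ND2", "GTP:gamma-phosphate")
    assert s.mean == pytest.approx(7.0)
    assert s.sd == pytest.approx(0.0)


def test_alternating_distance_statistics():
    topo, frames = _pair_trajectory([6.0, 8.0] * 3)
    s = monitor_distance(topo, frames, "A:1643:ND2", "GTP:gamma-phosphate")
    assert s.mean == pytest.approx(7.0)
    assert s.sd == pytest.approx(1.0)


def test_group_target_takes_nearest_atom():
    topo = _complex_from_atoms([
        ("ND2", "N", "ASN", 1, "A", (0, 0, 0)),
        ("PG", "P", "GTP", 900, "B", (9, 0, 0)),
        ("O1G", "O", "GTP", 900, "B", (5, 0, 0)),
    ])
    frames = topo.coords[None]
    s = monitor_distance(topo, np.repeat(frames, 2, axis=0),
                         "A:1:ND2", "GTP:gamma-phosphate")
    assert s.mean == pytest.approx(5.0)


def test_monitor_matches_per_frame_recomputation(toy_complex):
    traj = sd.generate_trajectory(toy_complex, 10, jitter_sd=0.2, seed=3)
    s = monitor_distance(toy_complex, traj.frames, "A:2:NZ", "B:2:OE1")
    i = next(k for k, a in enumerate(toy_complex.atoms)
             if (a.chain_id, a.residue_number, a.name) == ("A", 2, "NZ"))
    j = next(k for k, a in enumerate(toy_complex.atoms)
             if (a.chain_id, a.residue_number, a.name) == ("B", 2, "OE1"))
    for f in range(traj.n_frames):
        expect = np.linalg.norm(traj.frames[f, i] - traj.frames[f, j])
        assert s.distances[f] == pytest.approx(expect, abs=1e-12)


def test_unresolvable_spec_errors(toy_complex):
    with pytest.raises(StructureError):
        AtomSpec("A:999:XX").resolve(toy_complex)
    with pytest.raises(StructureError):
        AtomSpec("garbage").resolve(toy_complex)


# ---------------------------------------------------------------------------
# interaction_occupancy
# ---------------------------------------------------------------------------

def _half_present_frames(n_present, n_total):
    topo = _complex_from_atoms([
        ("NZ", "N", "LYS", 1, "A", (0, 0, 0)),
        ("OE1", "O", "GLU", 1, "B", (3.0, 0, 0)),
    ])
    frames = []
    for f in range(n_total):
        d = 3.0 if f < n_present else 15.0
        frames.append(np.array([[0, 0, 0], [d, 0, 0.0]]))
    return topo, np.stack(frames)


def test_occupancy_boundary_half_is_stable():
    topo, frames = _half_present_frames(100, 200)
    table = interaction_occupancy(topo, frames)
    sb = next(e for e in table if e.type == "salt_bridge")
    assert sb.occupancy == pytest.approx(0.5)
    assert sb.stable


def test_never_present_absent_from_table():
    topo, frames = _half_present_frames(0, 10)
    assert interaction_occupancy(topo, frames) == []


def test_occupancy_matches_frame_by_frame_bruteforce(toy_complex):
    traj = sd.generate_trajectory(toy_complex, 12, jitter_sd=0.3, seed=5)
    table = interaction_occupancy(toy_complex, traj.frames)
    for entry in table:
        count = 0
        dists = []
        for f in range(traj.n_frames):
            snap = toy_complex.with_coords(traj.frames[f])
            for r in detect_interactions(snap):
                if (r.type == entry.type
                        and r.receptor_residue == entry.receptor_residue
                        and r.ligand_residue == entry.ligand_residue):
                    count += 1
                    dists.append(r.distance)
        assert entry.occupancy == pytest.approx(count / traj.n_frames)
        assert entry.mean_distance == pytest.approx(np.mean(dists), abs=1e-12)


def test_occupancy_monotone_under_tighter_cutoff(toy_complex):
    traj = sd.generate_trajectory(toy_complex, 10, jitter_sd=0.4, seed=8)
    loose = interaction_occupancy(toy_complex, traj.frames,
                                  InteractionCriteria())
    tight = interaction_occupancy(
        toy_complex, traj.frames,
        InteractionCriteria(hbond_distance=3.0, salt_bridge_distance=3.2))
    loose_map = {(e.type, e.receptor_residue, e.ligand_residue): e.occupancy
                 for e in loose}
    for e in tight:
        key = (e.type, e.receptor_residue, e.ligand_residue)
        assert e.occupancy <= loose_map.get(key, 0.0) + 1e-12


# ---------------------------------------------------------------------------
# hot_regions
# ---------------------------------------------------------------------------

def test_two_separated_groups_give_two_regions():
    coords = [[0, 0, 0], [5, 0, 0], [8, 0, 0],
              [50, 0, 0], [55, 0, 0]]
    s = make_simple_structure(coords)
    regions = hot_regions([("A", i + 1) for i in range(5)], s,
                          linkage_cutoff=12.0)
    assert len(regions) == 2
    assert [len(r.members) for r in regions] == [3, 2]


def test_single_hotspot_single_region(toy_complex):
    regions = hot_regions([("A", 2)], toy_complex)
    assert len(regions) == 1 and regions[0].members == [("A", 2)]


def test_hot_regions_match_connected_components():
    rng = np.random.default_rng(17)
    coords = rng.uniform(0, 60, size=(12, 3))
    s = make_simple_structure(coords)
    spots = [("A", i + 1) for i in range(12)]
    cutoff = 15.0
    regions = hot_regions(spots, s, linkage_cutoff=cutoff)
    # brute-force connected components on the thresholded CA graph
    adj = {i: set() for i in range(12)}
    for i in range(12):
        for j in range(i + 1, 12):
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                adj[i].add(j)
                adj[j].add(i)
    seen, components = set(), []
    for i in range(12):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        components.append({("A", k + 1) for k in comp})
    got = [set(r.members) for r in regions]
    assert sorted(map(sorted, got)) == sorted(map(sorted, components))


def test_hot_regions_member_proximity_invariant():
    coords = [[0, 0, 0], [5, 0, 0], [40, 0, 0]]
    s = make_simple_structure(coords)
    regions = hot_regions([("A", 1), ("A", 2), ("A", 3)], s,
                          linkage_cutoff=12.0)
    for r in regions:
        if len(r.members) < 2:
            continue
        ca = {(a.chain_id, a.residue_number): a.coords for a in s.atoms}
        for m in r.members:
            assert any(np.linalg.norm(ca[m] - ca[o]) <= 12.0
                       for o in r.members if o != m)
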