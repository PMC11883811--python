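"""Protein structure model, PDB I/O, residue-range truncation and atom selection.

All geometry in the package operates on :class:`Structure`, an ordered list of
:class:`Atom` records carrying author (PDB) residue numbering verbatim so that
residue labels from the literature (e.g. N1643, R15) can be used directly.
Chains are assigned roles (``receptor`` / ``ligand`` / ``cofactor``) through
``Structure.chain_partition``; cofactors travel with the ligand side by
default in interface computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "Structure",
    "ResidueRangeSet",
    "StructureError",
    "read_structure",
    "read_trajectory_frames",
    "write_structure",
    "write_trajectory",
    "truncate",
    "select_atoms",
    "heavy",
    "chain",
    "residues",
    "name",
]

WATER_NAMES = {"HOH", "WAT", "TIP", "TIP3", "SPC", "DOD"}

ROLES = ("receptor", "ligand", "cofactor")


class StructureError(ValueError):
    """Raised for malformed structures, selections or files."""


@dataclass(frozen=True)
class Atom:
    """One atom record; residue numbering is author numbering, kept verbatim."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    coords: np.ndarray
    icode: str = ""
    hetero: bool = False

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.icode)

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise StructureError(
                f"atom {self.name} ({self.chain_id}:{self.residue_number}) has "
                f"non-finite or malformed coordinates"
            )
        object.__setattr__(self, "coords", c)


@dataclass
class Structure:
    """Ordered atom list with chain role assignments.

    Invariant: (chain_id, residue_number, icode, atom name) quadruples are
    unique within a structure.
    """

    atoms: list[Atom]
    id: str = ""
    chain_partition: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_number, a.icode, a.name)
            if key in seen:
                raise StructureError(f"duplicate atom identity {key}")
            seen.add(key)
        for c, role in self.chain_partition.items():
            if role not in ROLES:
                raise StructureError(f"unknown chain role {role!r} for chain {c!r}")

    # -- array views -------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float array of coordinates in Angstrom."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, id: str | None = None) -> "Structure":
        """Copy of this structure with replaced coordinates (same topology)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise StructureError(
                f"coordinate block shape {coords.shape} does not match "
                f"{self.n_atoms} atoms"
            )
        atoms = [replace(a, coords=c) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, id=id if id is not None else self.id,
                         chain_partition=dict(self.chain_partition))

    def subset(self, indices: Sequence[int], id: str | None = None) -> "Structure":
        atoms = [self.atoms[i] for i in indices]
        return Structure(atoms, id=id if id is not None else self.id,
                         chain_partition=dict(self.chain_partition))

    # -- residue / role helpers -------------------------------------------

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Residue identities in order of first appearance."""
        out: list[tuple[str, int, str]] = []
        seen: set[tuple] = set()
        for a in self.atoms:
            k = a.residue_key
            if k not in seen:
                seen.add(k)
                out.append(k)
        return out

    def residue_atom_indices(self) -> dict[tuple[str, int, str], list[int]]:
        table: dict[tuple[str, int, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            table.setdefault(a.residue_key, []).append(i)
        return table

    def role_of(self, chain_id: str) -> str:
        try:
            return self.chain_partition[chain_id]
        except KeyError:
            raise StructureError(
                f"chain {chain_id!r} has no role assigned in chain_partition"
            ) from None

    def role_indices(self, role: str, cofactor_with_ligand: bool = True) -> list[int]:
        """Atom indices whose chain carries ``role``.

        With ``cofactor_with_ligand`` (default) cofactor chains are folded
        into the ligand side, which is how interface computations treat them.
        """
        if not self.chain_partition:
            raise StructureError("structure has no chain role assignments")
        wanted = {role}
        if role == "ligand" and cofactor_with_ligand:
            wanted.add("cofactor")
        return [i for i, a in enumerate(self.atoms)
                if self.chain_partition.get(a.chain_id) in wanted]

    def copy(self) -> "Structure":
        return Structure(list(self.atoms), id=self.id,
                         chain_partition=dict(self.chain_partition))


@dataclass(frozen=True)
class ResidueRangeSet:
    """Inclusive (chain, start, end) residue ranges on author numbering."""

    ranges: tuple[tuple[str, int, int], ...]

    def __init__(self, ranges: Iterable[tuple[str, int, int]]):
        rs = tuple((str(c), int(a), int(b)) for c, a, b in ranges)
        for c, a, b in rs:
            if a > b:
                raise StructureError(f"range start {a} > end {b} on chain {c}")
        by_chain: dict[str, list[tuple[int, int]]] = {}
        for c, a, b in rs:
            by_chain.setdefault(c, []).append((a, b))
        for c, spans in by_chain.items():
            spans.sort()
            for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
                if a2 <= b1:
                    raise StructureError(
                        f"overlapping ranges {a1}-{b1} and {a2}-{b2} on chain {c}"
                    )
        object.__setattr__(self, "ranges", rs)

    def contains(self, chain_id: str, residue_number: int) -> bool:
        return any(c == chain_id and a <= residue_number <= b
                   for c, a, b in self.ranges)

    @classmethod
    def parse(cls, text: str) -> "ResidueRangeSet":
        """Parse ``"A:1537-1730,A:10-20"`` style range lists."""
        ranges = []
        for token in text.split(","):
            token = token.strip()
            if not token:
                continue
            try:
                chain_part, span = token.split(":")
                if "-" in span:
                    lo, hi = span.split("-")
                else:
                    lo = hi = span
                ranges.append((chain_part, int(lo), int(hi)))
            except ValueError:
                raise StructureError(f"cannot parse residue range {token!r}") from None
        return cls(ranges)


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _atoms_from_array(arr: bst.AtomArray, drop_waters: bool) -> list[Atom]:
    atoms: list[Atom] = []
    serials = (arr.get_annotation("atom_id")
               if "atom_id" in arr.get_annotation_categories()
               else np.arange(1, arr.array_length() + 1))
    for i in range(arr.array_length()):
        res_name = str(arr.res_name[i]).strip()
        if drop_waters and res_name in WATER_NAMES:
            continue
        atoms.append(Atom(
            serial=int(serials[i]),
            name=str(arr.atom_name[i]).strip(),
            element=str(arr.element[i]).strip() or "X",
            residue_name=res_name,
            residue_number=int(arr.res_id[i]),
            chain_id=str(arr.chain_id[i]).strip() or "A",
            coords=np.asarray(arr.coord[i], dtype=float),
            icode=str(arr.ins_code[i]).strip(),
            hetero=bool(arr.hetero[i]),
        ))
    return atoms


def _load_pdb(path: str | Path) -> PDBFile:
    path = Path(path)
    if not path.exists():
        raise StructureError(f"file not found: {path}")
    if path.stat().st_size == 0:
        raise StructureError(f"empty PDB file: {path}")
    try:
        return PDBFile.read(str(path))
    except Exception as exc:  # pragma: no cover - biotite error text varies
        raise StructureError(f"cannot parse {path}: {exc}") from exc


def read_structure(path: str | Path, format: str = "pdb", *,
                   keep_waters: bool = False,
                   chain_partition: Mapping[str, str] | None = None,
                   model: int = 1) -> Structure:
    """Read one model of a PDB file.

    Alternate locations are resolved to the highest-occupancy conformer.
    Waters are dropped unless ``keep_waters`` is set. Author residue
    numbering and insertion codes are preserved verbatim.
    """
    if format != "pdb":
        raise StructureError(f"unsupported format {format!r}")
    pdb = _load_pdb(path)
    try:
        arr = pdb.get_structure(model=model, altloc="occupancy",
                                extra_fields=["atom_id"])
    except Exception as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    atoms = _atoms_from_array(arr, drop_waters=not keep_waters)
    if not atoms:
        raise StructureError(f"no atoms read from {path}")
    return Structure(atoms, id=Path(path).stem,
                     chain_partition=dict(chain_partition or {}))


def read_trajectory_frames(path: str | Path, *, keep_waters: bool = False,
                           chain_partition: Mapping[str, str] | None = None,
                           ) -> tuple[Structure, np.ndarray]:
    """Read a multi-model PDB; returns (topology of model 1, frames array)."""
    pdb = _load_pdb(path)
    try:
        stack = pdb.get_structure(altloc="occupancy", extra_fields=["atom_id"])
    except Exception as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    first = stack[0] if isinstance(stack, bst.AtomArrayStack) else stack
    keep = np.ones(first.array_length(), dtype=bool)
    if not keep_waters:
        keep = ~np.isin(first.res_name, list(WATER_NAMES))
    topo = Structure(_atoms_from_array(first[keep], drop_waters=False),
                     id=Path(path).stem,
                     chain_partition=dict(chain_partition or {}))
    if isinstance(stack, bst.AtomArrayStack):
        frames = np.asarray(stack.coord[:, keep, :], dtype=float)
    else:
        frames = np.asarray(stack.coord[keep], dtype=float)[None]
    return topo, frames


def _array_from_structure(s: Structure, coords: np.ndarray | None = None
                          ) -> bst.AtomArray:
    n = s.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = s.coords if coords is None else np.asarray(coords, dtype=float)
    arr.chain_id = np.array([a.chain_id for a in s.atoms], dtype="U4")
    arr.res_id = np.array([a.residue_number for a in s.atoms], dtype=int)
    arr.ins_code = np.array([a.icode for a in s.atoms], dtype="U1")
    arr.res_name = np.array([a.residue_name for a in s.atoms], dtype="U5")
    arr.atom_name = np.array([a.name for a in s.atoms], dtype="U6")
    arr.element = np.array([a.element.upper() for a in s.atoms], dtype="U2")
    arr.hetero = np.array([a.hetero for a in s.atoms], dtype=bool)
    arr.set_annotation("atom_id", np.array([a.serial for a in s.atoms], dtype=int))
    return arr


def write_structure(s: Structure, path: str | Path) -> None:
    """Write a structure as a single-model PDB file."""
    pdb = PDBFile()
    pdb.set_structure(_array_from_structure(s))
    pdb.write(str(path))


def write_trajectory(topology: Structure, frames: np.ndarray,
                     path: str | Path) -> None:
    """Write coordinate frames as a multi-model PDB."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[1:] != (topology.n_atoms, 3):
        raise StructureError(
            f"frames shape {frames.shape} incompatible with topology "
            f"({topology.n_atoms} atoms)")
    stack = bst.AtomArrayStack(frames.shape[0], topology.n_atoms)
    template = _array_from_structure(topology)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = frames
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Truncation & selection
# ---------------------------------------------------------------------------

def truncate(s: Structure, keep: ResidueRangeSet) -> Structure:
    """Keep exactly the residues whose (chain, author number) fall in ``keep``.

    Residues with insertion codes are excluded unless their base number is
    listed; atom order is preserved.
    """
    if not keep.ranges:
        raise StructureError("empty ResidueRangeSet")
    idx = [i for i, a in enumerate(s.atoms)
           if keep.contains(a.chain_id, a.residue_number)]
    if not idx:
        raise StructureError("truncation selects zero atoms")
    return s.subset(idx)


# selectors -----------------------------------------------------------------

Selector = Callable[[Atom], bool]


def heavy() -> Selector:
    return lambda a: a.is_heavy


def chain(chain_id: str) -> Selector:
    return lambda a: a.chain_id == chain_id


def residues(keys: Iterable) -> Selector:
    """Match residues by (chain, number) pairs or bare numbers."""
    pairs: set[tuple[str, int]] = set()
    numbers: set[int] = set()
    for k in keys:
        if isinstance(k, int):
            numbers.add(k)
        else:
            c, n = k[0], k[1]
            pairs.add((str(c), int(n)))
    return lambda a: ((a.chain_id, a.residue_number) in pairs
                      or a.residue_number in numbers)


def name(atom_name: str) -> Selector:
    return lambda a: a.name == atom_name


def select_atoms(s: Structure, *selectors: Selector) -> list[int]:
    """Conjunction of selectors; returns atom indices in structure order."""
    for sel in selectors:
        if not callable(sel):
            raise StructureError(f"unknown selector {sel!r}")
    return [i for i, a in enumerate(s.atoms) if all(sel(a) for sel in selectors)]
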