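import numpy as np
import pytest

from bindmode import synthetic_data as sd
from bindmode.structure_io import Atom, Structure


def format_pdb_line(serial, name, resname, chain, resnum, x, y, z,
                    element, altloc=" ", occupancy=1.00, icode=" ",
                    record="ATOM"):
    atom_name = name if len(name) >= 4 else f" {name:<3s}"
    return (f"{record:<6s}{serial:>5d} {atom_name}{altloc}{resname:<3s} "
            f"{chain}{resnum:>4d}{icode}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{0.0:6.2f}"
            f"          {element:>2s}")


@pytest.fixture
def three_residue_pdb(tmp_path):
    lines = []
    serial = 1
    for i, res in enumerate(("ALA", "GLY", "SER"), start=1):
        for name, el, dx in (("N", "N", 0.0), ("CA", "C", 1.5),
                             ("C", "C", 2.9), ("O", "O", 3.5)):
            lines.append(format_pdb_line(serial, name, res, "A", i,
                                         i * 4.0 + dx, 0.0, 0.0, el))
            serial += 1
    path = tmp_path / "three.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    return path, serial - 1


@pytest.fixture
def toy():
    """Toy complex with planted salt bridge / H-bond / hydrophobic patch."""
    spec = sd.ToySpec(seed=1)
    complex, truth = sd.build_toy_complex(spec)
    return complex, truth


@pytest.fixture
def toy_complex(toy):
    return toy[0]


def make_simple_structure(coords, chain="A", resnum_start=1,
                          names=None, elements=None, resname="ALA",
                          partition=None):
    coords = np.asarray(coords, dtype=float)
    atoms = []
    for i, c in enumerate(coords):
        atoms.append(Atom(
            serial=i + 1,
            name=names[i] if names else "CA",
            element=elements[i] if elements else "C",
            residue_name=resname,
            residue_number=resnum_start + i,
            chain_id=chain,
            coords=c))
    return Structure(atoms, id="simple",
                     chain_partition=partition or {chain: "receptor"})
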