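import numpy as np
import pytest

from hingescan.structio import Residue, Structure


def _pdb_atom(serial, name, resname, chain, resnum, x, y, z,
              altloc=" ", occ=1.0, het=False, element=None):
    record = "HETATM" if het else "ATOM  "
    element = element or name[0]
    return (f"{record}{serial:5d} {name:^4s}{altloc}{resname:>3s} {chain}"
            f"{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00"
            f"          {element:>2s}")


@pytest.fixture
def pdb_three_residues(tmp_path):
    """Minimal 3-residue chain, no ligands."""
    lines = []
    serial = 1
    for i in range(3):
        x = 3.8 * i
        lines.append(_pdb_atom(serial, "N", "GLY", "A", i + 1, x, 1.2, 0.0)); serial += 1
        lines.append(_pdb_atom(serial, "CA", "GLY", "A", i + 1, x, 0.0, 0.0)); serial += 1
        lines.append(_pdb_atom(serial, "C", "GLY", "A", i + 1, x, -1.2, 0.5)); serial += 1
    path = tmp_path / "three.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


@pytest.fixture
def pdb_with_ligand(tmp_path):
    """3-residue chain plus one LIG heteroatom group and a water."""
    lines = []
    serial = 1
    for i in range(3):
        x = 3.8 * i
        lines.append(_pdb_atom(serial, "CA", "ALA", "A", i + 1, x, 0.0, 0.0)); serial += 1
        lines.append(_pdb_atom(serial, "CB", "ALA", "A", i + 1, x, 1.5, 0.0)); serial += 1
    lines.append(_pdb_atom(serial, "C1", "LIG", "A", 90, 0.0, 4.0, 0.0, het=True, element="C")); serial += 1
    lines.append(_pdb_atom(serial, "C2", "LIG", "A", 90, 1.0, 4.0, 0.0, het=True, element="C")); serial += 1
    lines.append(_pdb_atom(serial, "O", "HOH", "A", 91, 9.0, 9.0, 9.0, het=True, element="O"))
    path = tmp_path / "ligand.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


@pytest.fixture
def pdb_altloc(tmp_path):
    """One residue with an altloc'd CA: A at occ 0.6, B at occ 0.4."""
    lines = [
        _pdb_atom(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, altloc="A", occ=0.6),
        _pdb_atom(2, "CA", "ALA", "A", 1, 5.0, 0.0, 0.0, altloc="B", occ=0.4),
        _pdb_atom(3, "CA", "ALA", "A", 2, 3.8, 0.0, 0.0),
        _pdb_atom(4, "CA", "ALA", "A", 3, 7.6, 0.0, 0.0),
    ]
    path = tmp_path / "altloc.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


def dummy_chain(n, chain_id="A", start=1, spacing=3.8, offset=(0.0, 0.0, 0.0)):
    """Bead chain with straight-line coordinates (for profile/filter tests)."""
    residues = []
    off = np.asarray(offset, dtype=float)
    for i in range(n):
        xyz = np.array([spacing * i, 0.0, 0.0]) + off
        residues.append(Residue(chain_id=chain_id, number=start + i,
                                insertion_code="", name="ALA",
                                ca_coord=xyz, heavy_atoms=xyz[None, :].copy(),
                                atom_names=["CA"]))
    return residues


@pytest.fixture
def chain60():
    return Structure(id="chain60", residues=dummy_chain(60))


@pytest.fixture
def two_chain_structure():
    res = dummy_chain(10, "A") + dummy_chain(10, "B", offset=(0, 8, 0))
    return Structure(id="two_chains", residues=res)
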