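"""Structure reading, writing and superposition.

Structures are reduced to an ordered list of polymer residues (each with a
Calpha position and its heavy atoms) plus the heteroatom groups that may act
as ligands.  All coordinates are in Angstrom and residues are keyed by
``(chain_id, number, insertion_code)`` in author numbering, which is how
binding and hinge residues are reported in the literature.

Hydrogens are discarded everywhere: contact criteria are heavy-atom based
and most crystal structures do not resolve hydrogens anyway.  Only the first
model of a multi-model (NMR) file is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .errors import EmptyStructureError, FormatError, InsufficientPointsError

logger = logging.getLogger(__name__)

#: (chain_id, author residue number, insertion code) — the residue identity key.
ResId = tuple[str, int, str]

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M", "SEC": "U", "PYL": "O",
}


@dataclass
class Residue:
    """One polymer residue: identity, Calpha position and heavy atoms."""

    chain_id: str
    number: int
    insertion_code: str
    name: str
    ca_coord: np.ndarray
    heavy_atoms: np.ndarray          # (n, 3) float array, includes CA
    atom_names: list[str] = field(default_factory=list)

    @property
    def res_id(self) -> ResId:
        return (self.chain_id, self.number, self.insertion_code)

    @property
    def one_letter(self) -> str:
        return _THREE_TO_ONE.get(self.name, "X")


@dataclass
class LigandRecord:
    """A heteroatom group (heavy atoms only); drug status is an input flag."""

    het_code: str
    atoms: np.ndarray                # (n, 3)
    is_drug: bool = False
    chain_id: str = ""
    number: int = 0


@dataclass
class Structure:
    """An ordered polymer plus its ligand records."""

    id: str
    residues: list[Residue]
    ligands: list[LigandRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def N(self) -> int:
        return len(self.residues)

    @property
    def res_ids(self) -> list[ResId]:
        return [r.res_id for r in self.residues]

    @property
    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca_coord for r in self.residues], dtype=float)

    @property
    def chain_ids(self) -> list[str]:
        return [r.chain_id for r in self.residues]

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def index_of(self, res_id: ResId) -> int:
        try:
            return self.res_ids.index(res_id)
        except ValueError:
            raise KeyError(f"residue {res_id} not in structure {self.id}") from None


def _pick_altloc(atoms: Iterable[gemmi.Atom]) -> list[gemmi.Atom]:
    """Resolve altlocs per atom name: highest occupancy, ties -> first in file."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in atoms:
        prev = by_name.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            by_name[atom.name] = atom
    return list(by_name.values())


def read_structure(path: str | Path, chain_filter: Sequence[str] | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Polymer residues are separated from heteroatom groups; waters are
    dropped; altlocs resolve to the highest-occupancy conformer (ties: first
    in file); polymer residues lacking a Calpha are dropped with a warning.

    Raises :class:`FormatError` for unreadable files and
    :class:`EmptyStructureError` when no polymer residue survives.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, SystemError) as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    st.remove_hydrogens()
    model = st[0]

    residues: list[Residue] = []
    ligands: list[LigandRecord] = []
    for chain in model:
        if chain_filter is not None and chain.name not in chain_filter:
            continue
        for res in chain:
            if res.name in _WATER_NAMES:
                continue
            atoms = _pick_altloc(res)
            if not atoms:
                continue
            coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in atoms])
            names = [a.name for a in atoms]
            is_polymer = res.name in _STANDARD_AA or res.het_flag == "A"
            if is_polymer:
                if "CA" not in names:
                    logger.warning(
                        "%s: dropping residue %s %s%d%s (no Calpha)",
                        path.name, res.name, chain.name, res.seqid.num,
                        res.seqid.icode.strip(),
                    )
                    continue
                residues.append(Residue(
                    chain_id=chain.name,
                    number=res.seqid.num,
                    insertion_code=res.seqid.icode.strip(),
                    name=res.name,
                    ca_coord=coords[names.index("CA")].copy(),
                    heavy_atoms=coords,
                    atom_names=names,
                ))
            else:
                ligands.append(LigandRecord(
                    het_code=res.name,
                    atoms=coords,
                    chain_id=chain.name,
                    number=res.seqid.num,
                ))

    if not residues:
        raise EmptyStructureError(f"{path}: no polymer residues after filtering")
    residues.sort(key=lambda r: (r.chain_id, r.number, r.insertion_code))
    return Structure(id=path.stem, residues=residues, ligands=ligands)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure back out as a PDB file (fixtures, round-trips)."""
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    serial = 1

    def get_chain(cid: str) -> gemmi.Chain:
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
        return chains[cid]

    for res in structure.residues:
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
        gres.het_flag = "A"
        names = res.atom_names or [f"C{i}" for i in range(len(res.heavy_atoms))]
        for name, xyz in zip(names, res.heavy_atoms):
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(name[:1])
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            atom.serial = serial
            serial += 1
            gres.add_atom(atom)
        get_chain(res.chain_id).add_residue(gres)

    for lig in structure.ligands:
        gres = gemmi.Residue()
        gres.name = lig.het_code
        gres.seqid = gemmi.SeqId(lig.number or 1, " ")
        gres.het_flag = "H"
        for i, xyz in enumerate(lig.atoms):
            atom = gemmi.Atom()
            atom.name = f"C{i + 1}"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            atom.serial = serial
            serial += 1
            gres.add_atom(atom)
        get_chain(lig.chain_id or structure.residues[-1].chain_id).add_residue(gres)

    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def residue_table(structure: Structure, path: str | Path) -> None:
    """Dump the polymer residues as a TSV (chain, resnum, icode, name)."""
    with open(path, "w") as fh:
        fh.write("chain\tresnum\ticode\tname\n")
        for r in structure.residues:
            fh.write(f"{r.chain_id}\t{r.number}\t{r.insertion_code}\t{r.name}\n")


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Least-squares RMSD after optimal proper-rotation superposition.

    Both inputs are matched (n, 3) coordinate arrays, n >= 3.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise InsufficientPointsError("coordinate arrays must be matched (n, 3)")
    if a.shape[0] < 3:
        raise InsufficientPointsError(f"need >= 3 points, got {a.shape[0]}")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    # align_vectors solves the Kabsch problem with a proper rotation;
    # recompute the residual explicitly (the reported rssd loses precision
    # near zero).
    rot, _ = Rotation.align_vectors(a, b)
    diff = rot.apply(b) - a
    return float(np.sqrt((diff ** 2).sum() / a.shape[0]))
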