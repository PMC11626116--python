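"""Drug-binding residue identification and ensemble consolidation.

A residue coordinates a ligand when any of its heavy atoms lies within a
distance cutoff (default 4.5 A, inclusive) of any ligand heavy atom.  Across
an ensemble, per-member contact sets are mapped onto reference numbering and
a residue is kept when it contacts a drug in at least ``min_frequency`` of
the drug-bearing members — the consolidation that turns many partially
occupied poses into one consensus binding site.  Only ligands flagged
``is_drug`` count; ions, glycans and buffer molecules are parsed but ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .ensemble import Ensemble
from .errors import MalformedLigandError, NoDrugsError
from .structio import LigandRecord, ResId, Structure

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 4.5    # Angstrom, heavy-atom
DEFAULT_MIN_FREQUENCY = 0.10


@dataclass
class BindingSiteSet:
    """Consolidated drug-binding residues on reference numbering."""

    residues: set[ResId]
    frequency: dict[ResId, float]    # fraction of drug-bound members, (0, 1]

    @property
    def b(self) -> int:
        return len(self.residues)


def contact_residues(structure: Structure, ligand: LigandRecord,
                     cutoff: float = DEFAULT_CONTACT_CUTOFF) -> set[ResId]:
    """Residues with >= 1 heavy atom within ``cutoff`` of >= 1 ligand atom."""
    if len(ligand.atoms) == 0:
        raise MalformedLigandError(f"ligand {ligand.het_code} has no atoms")
    out: set[ResId] = set()
    lig = np.asarray(ligand.atoms, dtype=float)
    for res in structure.residues:
        d = cdist(np.asarray(res.heavy_atoms, dtype=float), lig)
        if (d <= cutoff).any():
            out.add(res.res_id)
    return out


def drug_contacts(structure: Structure,
                  cutoff: float = DEFAULT_CONTACT_CUTOFF) -> set[ResId]:
    """Union of contacts over all ligands flagged as drugs; empty (with a
    warning) when the structure carries none."""
    drugs = [lig for lig in structure.ligands if lig.is_drug]
    if not drugs:
        logger.warning("%s: no ligand flagged as drug", structure.id)
        return set()
    out: set[ResId] = set()
    for lig in drugs:
        out |= contact_residues(structure, lig, cutoff)
    return out


def consolidate_binding(ensemble: Ensemble,
                        cutoff: float = DEFAULT_CONTACT_CUTOFF,
                        min_frequency: float = DEFAULT_MIN_FREQUENCY) -> BindingSiteSet:
    """Consensus binding site over the drug-bearing members of an ensemble.

    The frequency denominator is the number of members that carry at least
    one drug; a residue is kept when frequency >= min_frequency.
    """
    drug_members = [m for m in ensemble.members
                    if any(l.is_drug for l in m.structure.ligands)]
    if not drug_members:
        raise NoDrugsError("no ensemble member carries a drug ligand")
    counts: dict[ResId, int] = {}
    for mem in drug_members:
        contacts = drug_contacts(mem.structure, cutoff)
        mapped = {mem.mapping[rid] for rid in contacts if rid in mem.mapping}
        for rid in mapped:
            counts[rid] = counts.get(rid, 0) + 1
    n = len(drug_members)
    frequency = {rid: c / n for rid, c in counts.items()
                 if c / n >= min_frequency}
    return BindingSiteSet(residues=set(frequency), frequency=frequency)


def binding_report(binding: BindingSiteSet, reference: Structure, path) -> None:
    """TSV report (chain, resnum, name, frequency)."""
    name_of = {r.res_id: r.name for r in reference.residues}
    with open(path, "w") as fh:
        fh.write("chain\tresnum\ticode\tname\tfrequency\n")
        for rid in sorted(binding.residues):
            fh.write(f"{rid[0]}\t{rid[1]}\t{rid[2]}\t{name_of.get(rid, '?')}\t"
                     f"{binding.frequency[rid]:.3f}\n")
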