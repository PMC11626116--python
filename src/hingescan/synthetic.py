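"""Synthetic two-domain "dumbbell" fixtures with planted ground truth.

The generator builds a bead-chain protein: two compact domains (residues on
a serpentine cubic lattice, 3.8 A spacing, so every bead has many contact
neighbours at the default GNM cutoff) joined by an extended straight linker.
Such a dumbbell has a clean slowest mode — the two domains move as
anticorrelated rigid blocks — with its single sign crossover inside the
linker, which is the planted hinge region.

A decoy "drug" ligand can be planted at a pocket (by default the interior
linker residues): one ligand atom is placed at a fixed offset from each
pocket residue's Calpha, at 3.5-4.0 A from that residue and > 4.5 A from
every other residue, so heavy-atom contact detection at the 4.5 A default
recovers exactly the planted pocket.

Geometry is deterministic given the seed; coordinate jitter (independent
Gaussian displacement per atom) emulates ensemble heterogeneity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .ensemble import Ensemble, EnsembleMember
from .structio import LigandRecord, ResId, Residue, Structure

_SPACING = 3.8   # A, consecutive-bead distance on lattice and linker


@dataclass
class DumbbellSpec:
    """Recipe for one dumbbell fixture; identical seed => identical output."""

    n_domain1: int = 40
    n_linker: int = 6
    n_domain2: int = 40
    domain_radius: float = 6.0       # informational; lattice is near-cubic
    linker_rise: float = _SPACING    # A per linker residue
    jitter_sd: float = 0.0           # A, per-atom Gaussian displacement
    seed: int = 0
    pocket_residues: list[int] | None = None   # residue numbers; None -> interior linker
    ligand_offset: float = 3.8       # A, ligand atom from pocket Calpha
    with_ligand: bool = True

    def __post_init__(self):
        if self.n_linker < 3:
            raise ValueError("n_linker must be >= 3")
        if not (3.5 <= self.ligand_offset <= 4.0):
            raise ValueError("ligand_offset must stay within 3.5-4.0 A")

    @property
    def n_total(self) -> int:
        return self.n_domain1 + self.n_linker + self.n_domain2

    @property
    def linker_range(self) -> tuple[int, int]:
        """First and last linker residue numbers (1-based, inclusive)."""
        return (self.n_domain1 + 1, self.n_domain1 + self.n_linker)

    @property
    def pocket(self) -> list[int]:
        if self.pocket_residues is not None:
            return list(self.pocket_residues)
        lo, hi = self.linker_range
        return list(range(lo + 1, hi))    # interior linker residues


def _serpentine_lattice(n: int) -> np.ndarray:
    """n points on a cubic lattice, ordered so consecutive points are
    one spacing apart (snake through rows and layers)."""
    side = int(np.ceil(n ** (1 / 3)))
    while side ** 2 * int(np.ceil(n / side ** 2)) < n:
        side += 1
    pts = []
    for z in range(int(np.ceil(n / side ** 2))):
        ys = range(side) if z % 2 == 0 else range(side - 1, -1, -1)
        for yi, y in enumerate(ys):
            flip = (z % 2) ^ (yi % 2)
            xs = range(side - 1, -1, -1) if flip else range(side)
            for x in xs:
                pts.append((x, y, z))
    return np.array(pts[:n], dtype=float) * _SPACING


def _base_coords(spec: DumbbellSpec) -> np.ndarray:
    """Deterministic (unjittered) Calpha coordinates of the full chain."""
    d1 = _serpentine_lattice(spec.n_domain1)
    d2 = _serpentine_lattice(spec.n_domain2)
    center_yz = d1[:, 1:].mean(axis=0)
    x0 = d1[:, 0].max() + _SPACING
    linker = np.column_stack([
        x0 + spec.linker_rise * np.arange(spec.n_linker),
        np.full(spec.n_linker, center_yz[0]),
        np.full(spec.n_linker, center_yz[1]),
    ])
    d2_offset = linker[-1, 0] + _SPACING - d2[:, 0].min()
    d2 = d2 + np.array([d2_offset, 0.0, 0.0])
    return np.vstack([d1, linker, d2])


def _is_connected(coords: np.ndarray, cutoff: float = 10.0) -> bool:
    adj = squareform(pdist(coords)) <= cutoff
    np.fill_diagonal(adj, False)
    n_comp, _ = connected_components(csr_matrix(adj), directed=False)
    return n_comp == 1


def make_dumbbell(spec: DumbbellSpec) -> Structure:
    """Build one dumbbell Structure (with optional planted ligand).

    Retries jittered generation up to 10 times if the contact graph at the
    default 10 A cutoff comes out disconnected; raises afterwards.
    """
    last_err = None
    for attempt in range(10):
        rng = np.random.default_rng(spec.seed + 100_000 * attempt)
        coords = _base_coords(spec)
        if spec.jitter_sd > 0:
            coords = coords + rng.normal(0.0, spec.jitter_sd, coords.shape)
        if _is_connected(coords):
            break
        last_err = f"disconnected at attempt {attempt}"
    else:
        raise RuntimeError(f"could not generate connected dumbbell: {last_err}")

    residues = [
        Residue(chain_id="A", number=i + 1, insertion_code="", name="ALA",
                ca_coord=coords[i].copy(), heavy_atoms=coords[i:i + 1].copy(),
                atom_names=["CA"])
        for i in range(spec.n_total)
    ]
    ligands = []
    if spec.with_ligand:
        pocket_idx = [p - 1 for p in spec.pocket]
        atoms = coords[pocket_idx] + np.array([0.0, 0.0, spec.ligand_offset])
        ligands.append(LigandRecord(het_code="DRG", atoms=atoms, is_drug=True,
                                    chain_id="A", number=spec.n_total + 1))
    meta = {
        "linker_range": spec.linker_range,
        "pocket": spec.pocket,
        "seed": spec.seed,
    }
    return Structure(id=f"dumbbell-{spec.seed}", residues=residues,
                     ligands=ligands, metadata=meta)


def make_ensemble(spec: DumbbellSpec, m: int, jitter_sd: float,
                  drug_fraction: float = 1.0) -> Ensemble:
    """m jittered copies of the dumbbell as an Ensemble with identity mapping.

    Member i uses seed ``spec.seed + i`` (1-based); the drug ligand is
    present in the first round(drug_fraction * m) members.  The reference is
    the unjittered dumbbell.
    """
    if m < 2:
        raise ValueError("need m >= 2 members")
    reference = make_dumbbell(replace(spec, jitter_sd=0.0, with_ligand=False))
    reference.id = f"dumbbell-ref-{spec.seed}"
    n_drug = round(drug_fraction * m)
    members = []
    identity: dict[ResId, ResId] = {r.res_id: r.res_id for r in reference.residues}
    for i in range(1, m + 1):
        mspec = replace(spec, jitter_sd=jitter_sd, seed=spec.seed + i,
                        with_ligand=(i <= n_drug))
        st = make_dumbbell(mspec)
        st.id = f"dumbbell-{spec.seed}-m{i}"
        rmsd = float(np.sqrt(np.mean(np.sum(
            (st.ca_coords - reference.ca_coords) ** 2, axis=1))))
        members.append(EnsembleMember(structure=st, mapping=dict(identity),
                                      seq_identity=100.0, z_score=50.0,
                                      rmsd_to_ref=rmsd))
    return Ensemble(reference=reference, members=members)


def write_ground_truth(spec: DumbbellSpec, path) -> None:
    """JSON sidecar with the planted linker range, pocket and seed."""
    payload = {
        "linker_range": list(spec.linker_range),
        "pocket": spec.pocket,
        "seed": spec.seed,
        "n_total": spec.n_total,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
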