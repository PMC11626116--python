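"""Ensemble handling: membership filters, mode matching, signature profiles.

Rather than trusting the mode shapes of a single crystal form, hinge calling
averages over an ensemble of drug-bound structural homologs mapped onto a
reference numbering.  Members are screened by sequence identity, (optional)
structural-similarity z-score and RMSD to the reference; each member's slow
modes are matched one-to-one to the reference modes by eigenvector overlap
(with sign alignment, since an eigenvector's global sign is arbitrary), and
the matched profiles are averaged position-wise into a signature profile
(mean +/- SD per reference residue).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .errors import DegenerateEnsembleError, EmptyEnsembleError
from .gnm import ModeProfile, ModeSet, modes_for_structure
from .structio import ResId, Structure, kabsch_rmsd

logger = logging.getLogger(__name__)


class CoverageError(ValueError):
    """Member alignment covers too little of the reference."""


@dataclass
class EnsembleMember:
    structure: Structure
    mapping: dict[ResId, ResId]          # member residue -> reference residue
    seq_identity: float                  # percent
    z_score: float | None = None         # structural-similarity z (metadata)
    rmsd_to_ref: float = 0.0             # Angstrom, over mapped Calpha pairs


@dataclass
class Ensemble:
    reference: Structure
    members: list[EnsembleMember]

    @property
    def m(self) -> int:
        return len(self.members)


@dataclass
class SignatureProfile:
    """Ensemble mean +/- SD of one matched mode on reference positions."""

    mode_index: int
    mean: np.ndarray         # NaN where coverage == 0
    sd: np.ndarray
    coverage: np.ndarray     # int, members contributing per position

    def as_profile(self) -> ModeProfile:
        values = np.where(np.isnan(self.mean), 0.0, self.mean)
        return ModeProfile(mode_index=self.mode_index, values=values)


@dataclass
class MembershipThresholds:
    """One filter profile: lower/upper bounds on identity and RMSD plus a
    minimum z-score (skipped with a warning when a member has no z)."""

    seq_identity_min: float = 85.0
    z_min: float | None = 10.0
    rmsd_max: float = 2.0
    rmsd_min: float = 0.0


@dataclass
class EnsembleFilterConfig:
    small: MembershipThresholds = field(default_factory=MembershipThresholds)
    large: MembershipThresholds = field(default_factory=lambda: MembershipThresholds(
        seq_identity_min=25.0, z_min=10.0, rmsd_max=float("inf")))
    size_boundary: int = 550     # reference N <= boundary -> small profile


def _member_passes(mem: EnsembleMember, th: MembershipThresholds) -> tuple[bool, str]:
    if mem.seq_identity <= th.seq_identity_min:
        return False, f"seq_identity {mem.seq_identity:.1f} <= {th.seq_identity_min}"
    if th.z_min is not None:
        if mem.z_score is None:
            logger.warning("%s: no z-score supplied; criterion skipped",
                           mem.structure.id)
        elif mem.z_score <= th.z_min:
            return False, f"z {mem.z_score:.1f} <= {th.z_min}"
    if not (th.rmsd_min <= mem.rmsd_to_ref < th.rmsd_max):
        return False, (f"rmsd {mem.rmsd_to_ref:.2f} outside "
                       f"[{th.rmsd_min}, {th.rmsd_max})")
    return True, ""


def filter_members(reference: Structure, candidates: list[EnsembleMember],
                   profile: str | None = None,
                   config: EnsembleFilterConfig | None = None) -> Ensemble:
    """Keep candidates passing the small- or large-protein criteria.

    ``profile`` is "small", "large", or None to auto-select by reference
    size (N <= size_boundary -> small).  Raises EmptyEnsembleError, listing
    each candidate's failed criterion, when nothing survives.
    """
    config = config or EnsembleFilterConfig()
    if profile is None:
        profile = "small" if reference.N <= config.size_boundary else "large"
    th = config.small if profile == "small" else config.large
    kept, reasons = [], []
    for mem in candidates:
        ok, why = _member_passes(mem, th)
        if ok:
            kept.append(mem)
        else:
            reasons.append(f"{mem.structure.id}: {why}")
            logger.info("dropping %s (%s)", mem.structure.id, why)
    if not kept:
        raise EmptyEnsembleError(
            "no member passed the filters:\n" + "\n".join(reasons))
    return Ensemble(reference=reference, members=kept)


_ALIGNER = Align.PairwiseAligner()
_ALIGNER.mode = "global"
_ALIGNER.match_score = 1
_ALIGNER.mismatch_score = -1
_ALIGNER.open_gap_score = -10
_ALIGNER.extend_gap_score = -0.5


def align_to_reference(reference: Structure, member: Structure) -> tuple[dict[ResId, ResId], float]:
    """Residue mapping by global sequence alignment, plus percent identity.

    A stand-in for an externally supplied (e.g. structural) alignment; used
    when no residue map is provided.  Identity is computed over aligned
    residue pairs.
    """
    aln = _ALIGNER.align(reference.sequence(), member.sequence())[0]
    ref_ids = reference.res_ids
    mem_ids = member.res_ids
    mapping: dict[ResId, ResId] = {}
    matches = pairs = 0
    ref_seq, mem_seq = reference.sequence(), member.sequence()
    for (rs, re_), (ms, me) in zip(*aln.aligned):
        for off in range(re_ - rs):
            mapping[mem_ids[ms + off]] = ref_ids[rs + off]
            pairs += 1
            if ref_seq[rs + off] == mem_seq[ms + off]:
                matches += 1
    identity = 100.0 * matches / pairs if pairs else 0.0
    return mapping, identity


def make_member(reference: Structure, structure: Structure,
                mapping: dict[ResId, ResId] | None = None,
                z_score: float | None = None) -> EnsembleMember:
    """Build an EnsembleMember, aligning and computing RMSD as needed."""
    if mapping is None:
        mapping, identity = align_to_reference(reference, structure)
    else:
        ref_name = {r.res_id: r.one_letter for r in reference.residues}
        mem_name = {r.res_id: r.one_letter for r in structure.residues}
        pairs = [(m, r) for m, r in mapping.items()
                 if m in mem_name and r in ref_name]
        matches = sum(1 for m, r in pairs if mem_name[m] == ref_name[r])
        identity = 100.0 * matches / len(pairs) if pairs else 0.0
    ref_xyz, mem_xyz = [], []
    for m_id, r_id in mapping.items():
        try:
            mem_xyz.append(structure.residues[structure.index_of(m_id)].ca_coord)
            ref_xyz.append(reference.residues[reference.index_of(r_id)].ca_coord)
        except KeyError:
            continue
    rmsd = kabsch_rmsd(np.array(ref_xyz), np.array(mem_xyz)) if len(ref_xyz) >= 3 else float("inf")
    return EnsembleMember(structure=structure, mapping=mapping,
                          seq_identity=identity, z_score=z_score,
                          rmsd_to_ref=rmsd)


def _mapped_indices(reference: Structure, member: EnsembleMember) -> tuple[np.ndarray, np.ndarray]:
    ref_pos = {rid: i for i, rid in enumerate(reference.res_ids)}
    mem_pos = {rid: i for i, rid in enumerate(member.structure.res_ids)}
    ref_idx, mem_idx = [], []
    for m_id, r_id in member.mapping.items():
        if m_id in mem_pos and r_id in ref_pos:
            ref_idx.append(ref_pos[r_id])
            mem_idx.append(mem_pos[m_id])
    order = np.argsort(ref_idx)
    return np.array(ref_idx)[order], np.array(mem_idx)[order]


def match_modes(reference_modes: ModeSet, member_modes: ModeSet, k: int,
                ref_idx: np.ndarray, mem_idx: np.ndarray,
                n_reference: int) -> list[tuple[int, float, float]]:
    """Pair each of the k slowest reference modes with a member mode.

    The search runs over the member's 2k slowest modes; assignment is
    one-to-one, greedy by descending |overlap| (normalized inner product
    over mapped positions), ties broken toward the lower member mode index.
    Returns, per reference mode 1..k, (member_mode_index, sign, overlap).

    Raises CoverageError when the mapping covers < 50% of the reference.
    """
    if len(ref_idx) < 0.5 * n_reference:
        raise CoverageError(
            f"mapping covers {len(ref_idx)}/{n_reference} reference residues")
    n_search = min(2 * k, member_modes.n_modes)
    ref_vecs = reference_modes.eigenvectors[ref_idx, :k]       # (n_map, k)
    mem_vecs = member_modes.eigenvectors[mem_idx, :n_search]   # (n_map, 2k)
    ref_norm = np.linalg.norm(ref_vecs, axis=0)
    mem_norm = np.linalg.norm(mem_vecs, axis=0)
    denom = np.outer(ref_norm, mem_norm)
    denom[denom == 0] = 1.0
    overlap = (ref_vecs.T @ mem_vecs) / denom                  # (k, 2k)

    pairing: dict[int, tuple[int, float, float]] = {}
    free_ref = set(range(k))
    free_mem = set(range(n_search))
    while free_ref and free_mem:
        best = None
        for j in sorted(free_ref):
            for l in sorted(free_mem):
                score = abs(overlap[j, l])
                if best is None or score > best[0] + 1e-15:
                    best = (score, j, l)
        _, j, l = best
        sign = 1.0 if overlap[j, l] >= 0 else -1.0
        pairing[j] = (l + 1, sign, abs(overlap[j, l]))
        free_ref.discard(j)
        free_mem.discard(l)
    return [pairing[j] for j in range(k)]


def signature_profile(ensemble: Ensemble, k: int,
                      cutoff: float = 10.0) -> list[SignatureProfile]:
    """Mean +/- SD of matched, sign-aligned member modes per reference residue.

    Members whose mapping covers < 50% of the reference are skipped with a
    warning.  Requires >= 2 contributing members; SD is the population SD of
    the contributing values at each position.
    """
    ref = ensemble.reference
    ref_modes = modes_for_structure(ref, cutoff=cutoff)
    n = ref.N
    sums = np.zeros((k, n))
    sq_sums = np.zeros((k, n))
    counts = np.zeros((k, n), dtype=int)
    contributed = 0
    for mem in ensemble.members:
        ref_idx, mem_idx = _mapped_indices(ref, mem)
        try:
            mem_modes = modes_for_structure(mem.structure, cutoff=cutoff)
            pairs = match_modes(ref_modes, mem_modes, k, ref_idx, mem_idx, n)
        except CoverageError as exc:
            logger.warning("skipping %s: %s", mem.structure.id, exc)
            continue
        for j, (mode_l, sign, _) in enumerate(pairs):
            vals = sign * mem_modes.eigenvectors[mem_idx, mode_l - 1]
            sums[j, ref_idx] += vals
            sq_sums[j, ref_idx] += vals ** 2
            counts[j, ref_idx] += 1
        contributed += 1
    if contributed < 2:
        raise DegenerateEnsembleError(
            f"only {contributed} member(s) matched; need >= 2")
    profiles = []
    for j in range(k):
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(counts[j] > 0, sums[j] / np.maximum(counts[j], 1), np.nan)
            var = sq_sums[j] / np.maximum(counts[j], 1) - np.square(
                np.where(counts[j] > 0, sums[j] / np.maximum(counts[j], 1), 0.0))
        sd = np.sqrt(np.clip(var, 0.0, None))
        sd[counts[j] == 0] = np.nan
        profiles.append(SignatureProfile(mode_index=j + 1, mean=mean, sd=sd,
                                         coverage=counts[j].copy()))
    return profiles


def signature_table(profiles: list[SignatureProfile], reference: Structure, path) -> None:
    """TSV export (chain, resnum, mode, mean, sd, coverage)."""
    with open(path, "w") as fh:
        fh.write("chain\tresnum\tmode\tmean\tsd\tcoverage\n")
        for prof in profiles:
            for i, rid in enumerate(reference.res_ids):
                fh.write(f"{rid[0]}\t{rid[1]}\t{prof.mode_index}\t"
                         f"{prof.mean[i]:.6f}\t{prof.sd[i]:.6f}\t{prof.coverage[i]}\n")
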