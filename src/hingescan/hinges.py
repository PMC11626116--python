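"""Hinge detection: sign crossovers in slow-mode profiles plus druggability
filters.

A hinge site is the region where a slow-mode profile changes sign: the
residues there mechanically coordinate the anticorrelated motion of the
flanking substructures.  Raw crossovers are then filtered, since not every
minimum of a mode shape is a usable hinge:

* crossovers close to chain termini are discarded (a drug bound there would
  perturb only the local tail, not the global motion);
* long contiguous stretches of near-zero amplitude are rigid blocks packed
  against the rest of the structure, not hinges — only their boundary
  residues can flex, so interior candidates are dropped;
* finally, near-zero residues immediately adjacent to a surviving crossover
  are annexed to the hinge site, since hinge action is shared by a short run
  of consecutive residues rather than a single pair.

The defaults for the four filter parameters are this package's calibration
(see docs/methods.md); all are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gnm import ModeProfile, ModeSet
from .structio import ResId, Structure


@dataclass
class HingeFilterParams:
    """Tunable knobs of the druggability filters.

    terminal_exclusion: residues to ignore at each chain end; ``None`` means
        max(5, round(0.04 * chain length)) per chain.
    rigid_block_min_len: minimum run length (residues) of |value| < delta
        that counts as a rigid block.
    delta_scale: delta = delta_scale * RMS(profile values); scale-free since
        profiles are unit-norm.
    extension_span: how many contiguous low-amplitude residues to annex on
        each side of a surviving crossover.
    """

    terminal_exclusion: int | None = None
    rigid_block_min_len: int = 20
    delta_scale: float = 0.5
    extension_span: int = 2


@dataclass
class HingeSet:
    """Filtered hinge residues per mode, with their union."""

    per_mode: dict[int, set[ResId]]
    provenance: dict[ResId, dict] = field(default_factory=dict)

    @property
    def union(self) -> set[ResId]:
        out: set[ResId] = set()
        for s in self.per_mode.values():
            out |= s
        return out

    @property
    def h(self) -> int:
        return len(self.union)


def _chain_runs(chain_ids: list[str]) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of consecutive same-chain runs."""
    runs = []
    start = 0
    for i in range(1, len(chain_ids) + 1):
        if i == len(chain_ids) or chain_ids[i] != chain_ids[start]:
            runs.append((start, i))
            start = i
    return runs


def find_crossovers(profile: ModeProfile,
                    chain_ids: list[str] | None = None) -> set[int]:
    """Positions flanking a sign change in the profile.

    For every consecutive same-chain pair with strictly opposite signs both
    positions are candidates; exact zeros adjacent to a sign change are
    candidates too.  Sign changes are never counted across chain boundaries.
    Returns 0-based positions into the profile.
    """
    v = np.asarray(profile.values, dtype=float)
    if len(v) < 3:
        raise ValueError("profile too short")
    if chain_ids is None:
        chain_ids = ["A"] * len(v)
    candidates: set[int] = set()
    for start, stop in _chain_runs(chain_ids):
        seg = v[start:stop]
        for i in range(len(seg) - 1):
            if seg[i] * seg[i + 1] < 0:
                candidates.add(start + i)
                candidates.add(start + i + 1)
        # exact zeros whose nearest nonzero neighbours have opposite signs
        for i in np.flatnonzero(seg == 0.0):
            left = seg[:i][seg[:i] != 0.0]
            right = seg[i + 1:][seg[i + 1:] != 0.0]
            if len(left) and len(right) and left[-1] * right[0] < 0:
                candidates.add(start + int(i))
    return candidates


def _terminal_width(params: HingeFilterParams, chain_len: int) -> int:
    if params.terminal_exclusion is not None:
        return params.terminal_exclusion
    return max(5, round(0.04 * chain_len))


def filter_hinges(candidates: set[int], profile: ModeProfile,
                  structure: Structure,
                  params: HingeFilterParams | None = None,
                  provenance: dict | None = None) -> set[int]:
    """Apply the terminal, rigid-block and extension filters in order.

    Returns surviving positions; ``provenance`` (if given) records per
    position which rule admitted or dropped it.
    """
    params = params or HingeFilterParams()
    prov = provenance if provenance is not None else {}
    v = np.asarray(profile.values, dtype=float)
    chain_ids = structure.chain_ids
    runs = _chain_runs(chain_ids)
    delta = params.delta_scale * float(np.sqrt(np.mean(v ** 2)))

    surviving: set[int] = set()
    for pos in candidates:
        prov.setdefault(pos, {"rule": "crossover", "filters": []})
        start, stop = next(r for r in runs if r[0] <= pos < r[1])
        t = _terminal_width(params, stop - start)
        if pos - start < t or stop - 1 - pos < t:
            prov[pos]["filters"].append("terminal:drop")
            continue
        prov[pos]["filters"].append("terminal:pass")
        surviving.add(pos)

    # rigid blocks: maximal same-chain runs of >= L residues with |v| < delta
    low = np.abs(v) < delta
    blocks: list[tuple[int, int]] = []
    for start, stop in runs:
        i = start
        while i < stop:
            if low[i]:
                j = i
                while j < stop and low[j]:
                    j += 1
                if j - i >= params.rigid_block_min_len:
                    blocks.append((i, j))
                i = j
            else:
                i += 1
    for bstart, bstop in blocks:
        for pos in list(surviving):
            if bstart < pos < bstop - 1:   # strictly interior
                surviving.discard(pos)
                prov[pos]["filters"].append("rigid_block:drop")
            elif pos in (bstart - 1, bstop):
                # crossover partner just outside the block: the flex point
                # is the block boundary itself, so collapse onto it
                surviving.discard(pos)
                prov[pos]["filters"].append("rigid_block:collapse_to_boundary")
        for pos in surviving & {bstart, bstop - 1}:
            prov[pos]["filters"].append("rigid_block:boundary_keep")

    # amplitude extension around surviving crossovers
    extended: set[int] = set()
    for pos in surviving:
        start, stop = next(r for r in runs if r[0] <= pos < r[1])
        for step in (-1, 1):
            p = pos
            for _ in range(params.extension_span):
                p += step
                if not (start <= p < stop) or abs(v[p]) >= delta:
                    break
                if p not in surviving:
                    extended.add(p)
    for pos in extended:
        prov.setdefault(pos, {"rule": "extension", "filters": ["extension:add"]})
    return surviving | extended


def hinge_set(profiles: list[ModeProfile] | ModeSet, structure: Structure,
              params: HingeFilterParams | None = None) -> HingeSet:
    """Per-mode filtered hinge sets for the selected slow modes.

    ``profiles`` may be a ModeSet (its ``selected_k`` slowest modes are
    used) or an explicit list of profiles, e.g. ensemble signature means.
    """
    if isinstance(profiles, ModeSet):
        k = profiles.selected_k or 1
        profiles = [profiles.profile(j) for j in range(1, k + 1)]
    per_mode: dict[int, set[ResId]] = {}
    provenance: dict[ResId, dict] = {}
    ids = structure.res_ids
    for prof in profiles:
        prov_pos: dict[int, dict] = {}
        cands = find_crossovers(prof, structure.chain_ids)
        kept = filter_hinges(cands, prof, structure, params, prov_pos)
        per_mode[prof.mode_index] = {ids[p] for p in kept}
        for p, rec in prov_pos.items():
            rec = dict(rec, mode=prof.mode_index)
            provenance.setdefault(ids[p], rec)
    return HingeSet(per_mode=per_mode, provenance=provenance)


def hinge_report(hinges: HingeSet, structure: Structure, path) -> None:
    """TSV report (chain, resnum, name, mode, filters passed)."""
    name_of = {r.res_id: r.name for r in structure.residues}
    with open(path, "w") as fh:
        fh.write("chain\tresnum\ticode\tname\tmode\tfilters\n")
        for mode in sorted(hinges.per_mode):
            for rid in sorted(hinges.per_mode[mode]):
                rec = hinges.provenance.get(rid, {})
                filters = ",".join(rec.get("filters", []))
                fh.write(f"{rid[0]}\t{rid[1]}\t{rid[2]}\t"
                         f"{name_of.get(rid, '?')}\t{mode}\t{filters}\n")


def selection_string(residues: set[ResId]) -> str:
    """Molecular-viewer selection string, e.g. ``chain A and resi 41+42``."""
    by_chain: dict[str, list[int]] = {}
    for cid, num, _ in sorted(residues):
        by_chain.setdefault(cid, []).append(num)
    parts = [f"(chain {cid} and resi {'+'.join(str(n) for n in nums)})"
             for cid, nums in sorted(by_chain.items())]
    return " or ".join(parts)
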