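"""End-to-end orchestration: modes -> hinges -> binding -> overlap.

Two entry points mirror the two ways the method is used: ``run_single``
analyses one drug-bound structure, ``run_ensemble`` averages mode profiles
over a set of homologs (signature dynamics) before calling hinges and
consolidates drug contacts across members.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .binding import BindingSiteSet, binding_report, consolidate_binding, drug_contacts
from .config import RunConfig
from .ensemble import (Ensemble, filter_members, make_member,
                       signature_profile, signature_table)
from .errors import FormatError, NoDrugsError
from .gnm import modes_for_structure
from .hinges import HingeSet, hinge_report, hinge_set, selection_string
from .stats import OverlapResult, overlap_result
from .structio import ResId, Structure, read_structure

logger = logging.getLogger(__name__)


def flag_drugs(structure: Structure, drug_codes: set[str]) -> int:
    """Mark ligands whose het code is in the allow-list; returns the count."""
    n = 0
    for lig in structure.ligands:
        lig.is_drug = lig.het_code in drug_codes
        n += lig.is_drug
    return n


def read_residue_list(path: str | Path) -> set[ResId]:
    """Residue list file: one ``chain:resnum`` (optionally ``:icode``) per line."""
    out: set[ResId] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(":")
        if len(parts) < 2:
            raise FormatError(f"bad residue-list line: {line!r}")
        out.add((parts[0], int(parts[1]), parts[2] if len(parts) > 2 else ""))
    return out


def _result_payload(result: OverlapResult, extra: dict | None = None) -> dict:
    payload = {
        "N": result.N, "h": result.h, "b": result.b, "s": result.s,
        "P": result.P, "P_formatted": result.formatted_p(),
        "e": result.e, "s_over_b": result.fraction_binding,
    }
    if extra:
        payload.update(extra)
    return payload


def _write_reports(out_dir: Path, result: OverlapResult, hinges: HingeSet,
                   binding: BindingSiteSet, reference: Structure,
                   config: RunConfig, extra: dict | None = None) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = _result_payload(result, extra)
    with open(out_dir / "result.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    hinge_report(hinges, reference, out_dir / "hinges.tsv")
    binding_report(binding, reference, out_dir / "binding.tsv")
    with open(out_dir / "selections.txt", "w") as fh:
        fh.write("hinges\t" + selection_string(hinges.union) + "\n")
        fh.write("binding\t" + selection_string(binding.residues) + "\n")
    config.save(out_dir / "config.yaml")


def run_single(structure_path: str | Path | Structure,
               config: RunConfig | None = None,
               drug_codes: set[str] | None = None,
               binding_list: set[ResId] | None = None,
               out_dir: str | Path | None = None) -> OverlapResult:
    """Single-structure pipeline.

    Binding residues come from heavy-atom drug contacts, or from an
    externally supplied residue list (which then replaces contact
    detection).  Raises NoDrugsError when neither is available.
    """
    config = config or RunConfig()
    if isinstance(structure_path, Structure):
        structure = structure_path
    else:
        structure = read_structure(structure_path)
    if drug_codes is not None:
        flag_drugs(structure, drug_codes)

    modes = modes_for_structure(structure, cutoff=config.gnm.cutoff,
                                sigma_min=config.gnm.sigma_min,
                                k_max=config.gnm.k_max)
    hinges = hinge_set(modes, structure, config.hinge)

    if binding_list is not None:
        binding = BindingSiteSet(residues=set(binding_list),
                                 frequency={r: 1.0 for r in binding_list})
    else:
        contacts = drug_contacts(structure, config.binding.cutoff)
        if not contacts:
            raise NoDrugsError(
                f"{structure.id}: no drug ligand and no binding list supplied")
        binding = BindingSiteSet(residues=contacts,
                                 frequency={r: 1.0 for r in contacts})

    result = overlap_result(hinges, binding, structure.N)
    if out_dir is not None:
        _write_reports(Path(out_dir), result, hinges, binding, structure,
                       config, {"selected_k": modes.selected_k,
                                "sigma": modes.sigma})
    return result


def load_manifest(manifest_path: str | Path, reference: Structure,
                  drug_codes: set[str] | None = None) -> list:
    """Read an ensemble manifest TSV/CSV into EnsembleMember candidates.

    Columns: path (required); chain, seq_identity, z_score, rmsd optional.
    Unreadable member files are skipped with a warning.
    """
    sep = "," if str(manifest_path).endswith(".csv") else "\t"
    df = pd.read_csv(manifest_path, sep=sep)
    if "path" not in df.columns:
        raise FormatError(f"{manifest_path}: manifest needs a 'path' column")
    base = Path(manifest_path).parent
    members = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        chain = None
        if "chain" in df.columns and pd.notna(row.get("chain")):
            chain = [str(row["chain"])]
        try:
            st = read_structure(p, chain_filter=chain)
        except (FormatError, OSError, Exception) as exc:  # noqa: BLE001
            logger.warning("skipping unreadable member %s: %s", p, exc)
            continue
        if drug_codes is not None:
            flag_drugs(st, drug_codes)
        z = float(row["z_score"]) if "z_score" in df.columns and pd.notna(row.get("z_score")) else None
        mem = make_member(reference, st, z_score=z)
        if "seq_identity" in df.columns and pd.notna(row.get("seq_identity")):
            mem.seq_identity = float(row["seq_identity"])
        if "rmsd" in df.columns and pd.notna(row.get("rmsd")):
            mem.rmsd_to_ref = float(row["rmsd"])
        members.append(mem)
    return members


def run_ensemble(ensemble_or_manifest, config: RunConfig | None = None,
                 reference: Structure | None = None,
                 drug_codes: set[str] | None = None,
                 second_set: set[ResId] | None = None,
                 out_dir: str | Path | None = None,
                 prefiltered: bool = False):
    """Ensemble pipeline: filtering, signature profiles, hinges on the mean
    profile, consolidated binding, overlap.

    Accepts either a ready Ensemble (``prefiltered`` skips membership
    filtering) or a manifest path plus ``reference``.  When ``second_set``
    is given (e.g. curated functional residues) a second OverlapResult
    against that set is returned as well.
    """
    config = config or RunConfig()
    if isinstance(ensemble_or_manifest, Ensemble):
        candidates = ensemble_or_manifest.members
        reference = ensemble_or_manifest.reference
    else:
        if reference is None:
            raise ValueError("manifest input requires a reference structure")
        candidates = load_manifest(ensemble_or_manifest, reference, drug_codes)
    if prefiltered and isinstance(ensemble_or_manifest, Ensemble):
        ensemble = ensemble_or_manifest
    else:
        ensemble = filter_members(reference, candidates,
                                  profile=config.ensemble_profile,
                                  config=config.ensemble)

    ref_modes = modes_for_structure(reference, cutoff=config.gnm.cutoff,
                                    sigma_min=config.gnm.sigma_min,
                                    k_max=config.gnm.k_max)
    k = ref_modes.selected_k
    signatures = signature_profile(ensemble, k, cutoff=config.gnm.cutoff)
    hinges = hinge_set([sig.as_profile() for sig in signatures],
                       reference, config.hinge)
    binding = consolidate_binding(ensemble, cutoff=config.binding.cutoff,
                                  min_frequency=config.binding.min_frequency)
    result = overlap_result(hinges, binding, reference.N)
    extra = {"m": ensemble.m, "selected_k": k, "sigma": ref_modes.sigma}

    second = None
    if second_set is not None:
        second_binding = BindingSiteSet(residues=set(second_set),
                                        frequency={r: 1.0 for r in second_set})
        second = overlap_result(hinges, second_binding, reference.N)

    if out_dir is not None:
        out_dir = Path(out_dir)
        _write_reports(out_dir, result, hinges, binding, reference, config, extra)
        signature_table(signatures, reference, out_dir / "signature.tsv")
        if second is not None:
            with open(out_dir / "second_set_result.json", "w") as fh:
                json.dump(_result_payload(second), fh, indent=2, sort_keys=True)
                fh.write("\n")
    if second is not None:
        return result, second
    return result
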