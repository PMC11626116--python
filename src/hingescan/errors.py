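"""Exception hierarchy; each class maps to a distinct CLI exit code."""


class HingescanError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class FormatError(HingescanError):
    """Input file could not be parsed as PDB/mmCIF or as a manifest."""

    exit_code = 2


class EmptyStructureError(HingescanError):
    """No polymer residues left after filtering."""

    exit_code = 3


class InsufficientPointsError(HingescanError):
    """Fewer than three matched points for superposition."""

    exit_code = 4


class DisconnectedStructureError(HingescanError):
    """GNM contact graph has more than one connected component."""

    exit_code = 5

    def __init__(self, components):
        self.components = components
        sizes = [len(c) for c in components]
        super().__init__(
            f"contact graph has {len(components)} components (sizes {sizes}); "
            "increase the cutoff or split the structure"
        )


class EmptyEnsembleError(HingescanError):
    """No ensemble member survived the membership filters."""

    exit_code = 6


class DegenerateEnsembleError(HingescanError):
    """Fewer than two matched members for a signature profile."""

    exit_code = 7


class MalformedLigandError(HingescanError):
    """Ligand record with no atoms."""

    exit_code = 8


class NoDrugsError(HingescanError):
    """No ensemble member carries a ligand flagged as a drug."""

    exit_code = 9


class NumberingMismatchError(HingescanError):
    """Residue sets use different numbering schemes."""

    exit_code = 10


class UndefinedEnrichmentError(HingescanError):
    """Enrichment requested with h = 0 or b = 0."""

    exit_code = 11
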