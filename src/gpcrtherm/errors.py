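"""Exception hierarchy for the package."""


class GpcrthermError(Exception):
    """Base class for all package errors."""


class FormatError(GpcrthermError):
    """Input file could not be parsed."""


class EmptyStructureError(GpcrthermError):
    """A structure (or the residues surviving a filter) is empty."""


class MissingChainError(GpcrthermError):
    """Requested chain is absent from the structure."""


class MissingResidueError(GpcrthermError):
    """Requested residue is absent from the structure."""


class WildtypeMismatchError(GpcrthermError):
    """Residue found at the mutation site does not match the stated wild type."""


class InvalidResidueError(GpcrthermError):
    """Amino-acid code is not one of the 20 standard residues."""


class DataIntegrityError(GpcrthermError):
    """A packaged lookup table is missing a required entry."""


class DataConflictError(GpcrthermError):
    """Records disagree on facts that must be consistent (e.g. wild-type identity)."""


class FeatureComputationError(GpcrthermError):
    """A structural feature backend failed for a specific residue."""


class ConfigurationError(GpcrthermError):
    """Run configuration is incomplete or inconsistent."""


class SchemaError(GpcrthermError):
    """A feature table does not match the expected column schema."""


class InsufficientDataError(GpcrthermError):
    """Not enough records to perform the requested operation."""


class MutationParseError(GpcrthermError):
    """A mutation line does not follow the '<wt><position><mt> <chain>' format."""
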