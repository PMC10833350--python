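"""Exception hierarchy for the auditing pipeline.

Exit-code mapping used by the CLI: I/O and parse failures exit 2,
analysis failures exit 1.
"""


class LowresAuditError(Exception):
    """Base class for all package errors."""


class StructureParseError(LowresAuditError):
    """A coordinate file could not be parsed under the named standard."""


class EmptyModelError(LowresAuditError):
    """An operation produced or received a model with zero protein residues."""


class ChainNotFoundError(LowresAuditError, KeyError):
    """A requested chain ID is absent from the model."""


class EncodingError(LowresAuditError):
    """A field cannot be represented in the fixed-width PDB format."""


class ConfidenceRangeError(LowresAuditError):
    """A pLDDT value read from the B-factor column is outside [0, 100]."""


class UndefinedDihedralError(LowresAuditError, ValueError):
    """Collinear or coincident points leave the dihedral undefined."""


class ComparisonError(LowresAuditError):
    """Two models share no pairable residues."""


class ConfigurationError(LowresAuditError):
    """A contour table or run configuration is malformed."""


class BuildSpecError(LowresAuditError, ValueError):
    """A synthetic-chain build specification is invalid."""


class InjectionError(LowresAuditError, ValueError):
    """A perturbation cannot be applied at the requested position."""
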