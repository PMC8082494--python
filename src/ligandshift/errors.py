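"""Exception hierarchy.

ConfigError maps to CLI exit code 2, DataError (and subclasses) to 3.
"""


class LigandShiftError(Exception):
    """Base class for all package errors."""


class ConfigError(LigandShiftError):
    """Invalid configuration or parameters."""


class DataError(LigandShiftError):
    """Invalid or inconsistent input data."""


class SchemaError(DataError):
    """A table does not have the expected columns."""


class AlphabetError(DataError):
    """A residue outside the 20 standard amino acids."""


class ReferenceMismatchError(DataError):
    """A variant's reference residue does not match the sequence."""


class CoordinateError(DataError):
    """Peptide or variant coordinates inconsistent with sequence."""


class UnmappedPeptideError(DataError):
    """A peptide cannot be mapped to any database entry."""


class InsufficientReplicatesError(DataError):
    """Too few replicates for the requested statistic."""


class ImputationError(DataError):
    """Imputation impossible (e.g. a fully missing sample column)."""


class StandardNotDetectedError(DataError):
    """Heavy-standard area missing or non-positive."""


class DependencyError(DataError):
    """A required upstream result was not supplied."""
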