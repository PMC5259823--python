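"""Exception hierarchy for the qipi package."""


class QipiError(Exception):
    """Base class for all package-specific errors."""


class FormatError(QipiError):
    """Input file cannot be parsed in the expected format."""


class EmptyStructureError(QipiError):
    """A structure contains no protein residues (or no surface residues)."""


class ParameterError(QipiError, ValueError):
    """A numeric parameter is outside its admissible range."""


class StateError(QipiError):
    """An operation was called before a required computation (e.g. ASA)."""


class AlignmentError(QipiError):
    """An auxiliary file (DSSP, PSSM) does not align with the structure."""


class PartitionError(QipiError):
    """A complex partition is invalid (empty or overlapping sides)."""


class GeometryError(QipiError):
    """A residue lacks the atoms needed for a geometric computation."""


class ConstantsError(QipiError, KeyError):
    """A required entry is missing from a packaged constant table."""


class ConfigError(QipiError):
    """Invalid run/training configuration."""
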