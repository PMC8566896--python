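"""Exception hierarchy.

``ValidationError`` (and subclasses) signal malformed inputs or broken
preconditions and map to CLI exit code 2; every other
``DomChemodivError`` maps to exit code 1.
"""


class DomChemodivError(Exception):
    """Base class for all package errors."""


class ValidationError(DomChemodivError, ValueError):
    """Input data or configuration violates a documented contract."""


class SchemaError(ValidationError):
    """A delimited-text file is missing columns or has malformed rows."""


class DuplicateIdError(ValidationError):
    """Duplicate feature/sample identifiers where uniqueness is required."""


class ChemistryError(ValidationError):
    """A chemically impossible formula (e.g. negative DBE)."""


class UnsupportedIonModeError(ValidationError):
    """Ion mode other than singly deprotonated [M-H]- was requested."""


class NoPeaksInWindowError(ValidationError):
    """No peaks remain after applying the m/z analysis window."""


class ZeroVarianceError(ValidationError):
    """A constant vector where a correlation requires variance."""


class SampleMismatchError(ValidationError):
    """Two paired tables do not share an identical sample set."""


class EmptySampleError(ValidationError):
    """A sample column with zero total counts/intensity."""


class TreeCoverageError(ValidationError):
    """A phylogeny does not contain every observed OTU."""


class InfeasibleDesignError(DomChemodivError):
    """The synthetic design could not be realized within bounded attempts."""
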