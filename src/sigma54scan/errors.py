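"""Exception hierarchy.

All package errors derive from :class:`Sigma54ScanError` so callers can
catch one type; most also derive from ``ValueError`` because they signal
invalid inputs rather than internal failures.
"""


class Sigma54ScanError(Exception):
    """Base class for all sigma54scan errors."""


class InputError(Sigma54ScanError, ValueError):
    """Invalid argument or malformed in-memory input."""


class AlignmentError(InputError):
    """Training sites of unequal length."""


class AmbiguousBaseError(InputError):
    """A non-ACGT base where an unambiguous base is required."""


class UnscorableWindowError(AmbiguousBaseError):
    """Window contains an ambiguous base; the caller should skip it."""


class PWMFormatError(Sigma54ScanError, ValueError):
    """Malformed or invalid PWM file."""


class FastaError(Sigma54ScanError, ValueError):
    """Malformed FASTA input."""


class PTTError(Sigma54ScanError, ValueError):
    """Malformed PTT annotation table."""
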