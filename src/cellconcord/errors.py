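"""Exception hierarchy.

Each class maps to a distinct CLI exit code so that shell pipelines can
distinguish bad inputs (2), I/O trouble (3) and statistics that are
undefined for the given data (4).
"""


class CellConcordError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class FormatError(CellConcordError):
    """A file does not conform to the expected CSV dialect."""

    exit_code = 2


class ValidationError(CellConcordError):
    """Input values violate a precondition or invariant."""

    exit_code = 2


class IOError_(CellConcordError):
    """Reading or writing an artifact failed."""

    exit_code = 3


class UndefinedStatisticError(CellConcordError):
    """The requested statistic is undefined for this input.

    Examples: kappa on an empty confusion matrix, expected agreement of 1,
    a class ratio with a zero denominator.  Reported explicitly instead of
    silently returning 0 or NaN.
    """

    exit_code = 4


class GenerationError(CellConcordError):
    """Synthetic generation could not satisfy its constraints."""

    exit_code = 2
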