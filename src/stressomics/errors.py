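"""Exception hierarchy for stressomics.

Every guarded precondition in the pipeline raises a subclass of
:class:`StressomicsError`, so callers can catch pipeline failures without
masking programming errors.
"""


class StressomicsError(Exception):
    """Base class for all stressomics errors."""


class InvalidSpecError(StressomicsError, ValueError):
    """A simulation spec violates its invariants."""


class InsufficientDataError(StressomicsError, ValueError):
    """Too few observations to apply the requested operation."""


class UndefinedRatioError(StressomicsError, ZeroDivisionError):
    """SI ratio undefined because the no-target time is zero."""


class DegenerateTableError(StressomicsError, ValueError):
    """A contingency table has a zero margin."""


class InvalidMatrixError(StressomicsError, ValueError):
    """An omics matrix violates its invariants (e.g. zero library size)."""


class InvalidInputError(StressomicsError, ValueError):
    """Generic invalid input to an integration or enrichment operation."""


class UndefinedScoreError(StressomicsError, ValueError):
    """A score (ES, activation z) is undefined for the given inputs."""


class ParseError(StressomicsError, ValueError):
    """A text input file is malformed."""
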