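"""Exception hierarchy.

Every error raised by the package derives from :class:`PylorthoError`, so
callers can catch one type at a pipeline boundary while tests can assert the
specific failure mode.
"""


class PylorthoError(Exception):
    """Base class for all package errors."""


class AlignmentShapeError(PylorthoError):
    """Sequences in an alignment do not share a common column space."""


class DuplicateIdError(PylorthoError):
    """Two records carry the same identifier."""


class EmptyInputError(PylorthoError):
    """An input file or collection contains no usable records."""


class UndefinedIdentityError(PylorthoError):
    """Percent identity is undefined (e.g. both sequences are all-gap)."""


class InsufficientInputError(PylorthoError):
    """An operation needs more records than were supplied."""


class MissingReferenceError(PylorthoError):
    """A named reference sequence is absent from the alignment."""


class WindowRangeError(PylorthoError):
    """A domain window falls outside the reference sequence."""


class InvalidMatrixError(PylorthoError):
    """A matrix violates symmetry, range, or shape requirements."""


class TableParseError(PylorthoError):
    """A delimited table could not be parsed; carries row/column context."""


class InvalidControlError(PylorthoError):
    """The normalisation control value is non-positive."""


class IncompleteDataError(PylorthoError):
    """A computation requires measured values that are missing."""


class SetOrderError(PylorthoError):
    """An orthogonal-set operation received an invalid tuple order."""


class MetadataError(PylorthoError):
    """Entity metadata is missing or inconsistent."""


class EmptyStratumError(PylorthoError):
    """No data points fall in the requested identity stratum."""


class FeasibilityError(PylorthoError):
    """Simulation parameters cannot be realised (identity bands infeasible)."""


class ParameterError(PylorthoError):
    """Simulation parameters are mutually inconsistent."""


class PipelineStageError(PylorthoError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
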