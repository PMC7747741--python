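"""Exception hierarchy shared by all stages."""


class MethsigError(Exception):
    """Base class for all package errors."""


class FormatError(MethsigError):
    """A file could not be parsed in the declared format."""


class ValidationError(MethsigError):
    """Input data violate a structural contract (shapes, ids, finiteness)."""


class ConfigurationError(MethsigError):
    """A required column/key/option is missing or inconsistent."""


class ParameterError(MethsigError):
    """A numeric parameter is out of its admissible range."""


class NoKneeError(MethsigError):
    """The sorted kNN-distance curve has no derivative exceedance.

    Raised when the scaled derivative never crosses the threshold (for
    example a linear or constant curve); supply ``eps`` manually instead.
    """


class StageError(MethsigError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")
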