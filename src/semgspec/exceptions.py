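"""Exception hierarchy.

All package errors derive from :class:`SemgSpecError` so callers can catch
one base type; parameter/input problems additionally subclass ``ValueError``
for interoperability with generic callers.
"""


class SemgSpecError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(SemgSpecError, ValueError):
    """A configuration or call parameter violates an operation precondition."""


class InvalidInputError(SemgSpecError, ValueError):
    """Input data violate an operation precondition (shape, grid, sign...)."""


class AliasingError(InvalidParameterError):
    """Sampling rate below twice the top of the analysis band."""


class UndefinedMedianError(InvalidInputError):
    """Median frequency requested for a spectrum with zero total power."""


class UndefinedVafError(InvalidInputError):
    """VAF requested against an all-zero reference matrix."""


class InsufficientDataError(InvalidInputError):
    """Too few observations for the requested statistic."""


class NoRankFoundError(SemgSpecError):
    """No tested rank reached the VAF threshold.

    Carries the VAF curve measured for every tested rank so callers can
    inspect how far the search got.
    """

    def __init__(self, message: str, vaf_curve: dict):
        super().__init__(message)
        self.vaf_curve = dict(vaf_curve)


class FormatError(SemgSpecError):
    """A file to be read does not conform to the expected on-disk format."""


class StageError(SemgSpecError):
    """A pipeline stage failed; names the stage and the trial it was processing."""

    def __init__(self, stage: str, trial_id: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed for trial '{trial_id}': {cause}")
        self.stage = stage
        self.trial_id = trial_id
        self.cause = cause
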