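"""Exception hierarchy.

Every error raised by lesionet derives from :class:`LesionetError`, so callers
(and the CLI) can distinguish pipeline failures from programming errors.
"""


class LesionetError(Exception):
    """Base class for all lesionet errors."""


class SchemaError(LesionetError):
    """A table or file does not have the expected columns/structure."""


class ValidationError(LesionetError):
    """Values present but invalid (negative volume, unknown group label, ...)."""


class InsufficientDataError(LesionetError):
    """Too few subjects/observations for the requested computation."""


class DegenerateDataError(LesionetError):
    """Observed data degenerate for the computation (e.g. zero-variance region)."""


class UndefinedScoreError(LesionetError):
    """A behavioral score is undefined for the given input (e.g. <3 visits)."""


class CohortSpecError(LesionetError):
    """A synthetic cohort specification is internally inconsistent."""
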