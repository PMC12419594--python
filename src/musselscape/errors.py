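"""Exception hierarchy used across the pipeline."""


class MusselscapeError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(MusselscapeError, ValueError):
    """A configuration object violates its invariants."""


class DataError(MusselscapeError, ValueError):
    """Input data violate a schema or referential-integrity constraint."""


class DegenerateInputError(MusselscapeError, ValueError):
    """An operation received input on which its result is undefined
    (constant scores, empty candidate sets, ...)."""


class FitError(MusselscapeError, RuntimeError):
    """Model fitting could not be carried out."""


class NotFittedError(MusselscapeError, RuntimeError):
    """Prediction requested from an unfitted model."""
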