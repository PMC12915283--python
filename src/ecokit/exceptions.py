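"""Exception hierarchy for the pipeline.

Configuration problems (bad parameter values) and input problems (bad data)
are kept distinct so callers can tell a mis-set flag from an unusable file.
"""


class EcokitError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(EcokitError, ValueError):
    """A parameter or config field is invalid."""


class InputError(EcokitError, ValueError):
    """Input data violate a precondition of an operation."""


class CleaningError(EcokitError):
    """Artifact removal left no usable samples."""


class EpochingError(InputError):
    """One or more stimulus events cannot be epoched from the trace."""

    def __init__(self, message, offending_events=()):
        super().__init__(message)
        self.offending_events = list(offending_events)


class NormalizationError(EcokitError):
    """Epoch normalization is undefined (e.g. zero prestimulus variance)."""


class FitError(EcokitError):
    """Psychometric fit preparation or optimization failed."""
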