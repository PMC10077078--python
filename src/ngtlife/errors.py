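"""Package-wide exception types."""


class NgtLifeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NgtLifeError, ValueError):
    """A configuration object violates its invariants."""


class EmptyCohortError(NgtLifeError, ValueError):
    """A filter or drift scenario produced an empty cohort."""


class NotFittedError(NgtLifeError, RuntimeError):
    """A model or reducer was used before being fit."""
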