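"""Exception hierarchy shared across the pipeline.

Validation errors map to CLI exit code 2, numerical audit failures to 3.
"""


class CobenefitsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CobenefitsError, ValueError):
    """A configuration object is degenerate or self-inconsistent."""


class ValidationError(CobenefitsError, ValueError):
    """Inputs to an operation violate its contract (shape, units, labels)."""


class GenerationError(CobenefitsError, RuntimeError):
    """Synthetic-world generation could not satisfy its postconditions."""


class AuditError(CobenefitsError, RuntimeError):
    """A conservation/consistency audit exceeded tolerance."""
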