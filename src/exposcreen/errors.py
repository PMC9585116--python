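"""Exception hierarchy for the suspect-screening pipeline."""


class ExposcreenError(Exception):
    """Base class for all package errors."""


class ConfigError(ExposcreenError, ValueError):
    """A configuration value is missing, malformed, or inconsistent."""


class ValidationError(ExposcreenError, ValueError):
    """Input data violate a precondition (bad schema, negative abundance, ...)."""


class AnnotationError(ExposcreenError, ValueError):
    """Isomer assignment is impossible (e.g. more chemicals than isomers)."""


class UndefinedStatisticError(ExposcreenError, ValueError):
    """A statistic is undefined for the given input (constant vector, n too small)."""
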