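"""Exception hierarchy shared by all modules."""


class DosagecompError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DosagecompError, ValueError):
    """A file could not be parsed (malformed line, wrong column count, ...)."""


class ValidationError(DosagecompError, ValueError):
    """A parsed table or object violates an invariant (duplicate key, negative value, ...)."""


class ConfigError(DosagecompError, ValueError):
    """A configuration value is outside its allowed domain."""


class DegenerateFitError(DosagecompError, RuntimeError):
    """A model fit collapsed (e.g. a mixture component variance underflow)."""
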