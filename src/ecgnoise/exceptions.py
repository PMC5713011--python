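"""Exception hierarchy.

All package errors derive from :class:`EcgNoiseError` so callers (and the
CLI) can catch one base class and map it to an exit code.
"""


class EcgNoiseError(Exception):
    """Base class for all errors raised by ecgnoise."""


class FormatError(EcgNoiseError):
    """A file could not be parsed or is internally inconsistent."""


class ValidationError(EcgNoiseError, ValueError):
    """Input data violates a documented invariant."""


class InsufficientDataError(EcgNoiseError):
    """The signal is too short for the requested operation."""


class ConfigurationError(EcgNoiseError):
    """Parameter values are inconsistent (e.g. notch frequency above Nyquist)."""
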