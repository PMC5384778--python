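"""Exception hierarchy.

Every error the package raises derives from :class:`DosewarpError` so callers
(and the CLI) can map failures onto exit codes: usage problems are raised by
click itself, data/format problems derive from :class:`DataError`, and
numerical/degenerate failures derive from :class:`NumericalError`.
"""


class DosewarpError(Exception):
    """Base class for all package errors."""


class DataError(DosewarpError):
    """A problem with input data or files (exit code 3)."""


class FormatError(DataError):
    """Unreadable, unsupported, or malformed file."""


class ParseError(DataError):
    """Malformed text input (CSV landmarks, parameter files, JSON transforms)."""


class GeometryError(DataError):
    """Inconsistent or incompatible image geometry."""


class ValidationError(DataError):
    """Input violates a documented invariant (e.g. negative dose)."""


class NumericalError(DosewarpError):
    """A numerical failure during computation (exit code 4)."""


class ConfigError(DosewarpError):
    """Invalid configuration value (unknown interpolator, bad level count...)."""


class DegenerateConfigurationError(NumericalError):
    """Point set too small / collinear / rank deficient for the requested fit."""


class UndefinedMetricError(NumericalError):
    """Similarity metric undefined for the given inputs (e.g. constant images)."""


class RegistrationError(NumericalError):
    """Registration could not proceed (empty overlap, non-finite objective)."""
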